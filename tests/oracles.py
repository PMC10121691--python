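"""Independent straight-line recomputations used as test oracles.

These deliberately re-derive results with plain arithmetic, separate from
the package's implementation paths.
"""
import math


def hand_stepped_toy_yield(weather, m, soil, g, sp, c) -> float:
    """Spreadsheet-style recomputation of a short constant-stage season.

    Valid for seasons where the soil never sits saturated for the flooding
    threshold (flood factor 1 throughout).
    """
    eff_cap = soil.capacity_mm * sp.sw_cap_scale
    area = 1e4 / m.density
    sw = soil.init_fraction * eff_cap
    cum_gdd, stage = 0.0, "veg"
    leaf, root, stem, grain = c.seed_leaf, c.seed_root, c.seed_stem, 0.0

    def es(t):
        return 0.6108 * math.exp(17.27 * t / (t + 237.3))

    n_days = m.harvest_doy - m.plant_doy + 1
    offset = m.plant_doy - int(weather.doy[0])
    for day in range(n_days):
        i = offset + day
        tmax, tmin = float(weather.tmax[i]), float(weather.tmin[i])
        prcp = float(weather.prcp[i])
        srad, ea = float(weather.srad[i]), float(weather.vp[i])
        hi = min(max(tmax, c.tbase), c.tcap)
        lo = min(max(tmin, c.tbase), c.tcap)
        cum_gdd += max(0.0, (hi + lo) / 2 - c.tbase)
        if stage == "veg" and cum_gdd >= g.gdd_flower:
            stage = "rep"
        if stage == "rep" and cum_gdd >= g.gdd_mature:
            break
        vpd = max(0.0, (es(tmax) + es(tmin)) / 2 - ea)
        lai = leaf * g.sla / area
        f_int = 1 - math.exp(-c.k_ext * lai)
        u_pot = g.u_max * root * vpd
        avail = max(0.0, sw - c.wilting_fraction * eff_cap)
        uptake = min(u_pot, avail * area)
        drought = uptake / u_pot if u_pot > 0 else 1.0
        uptake_mm = uptake / area
        runoff = sp.runoff_coeff * prcp
        evap = sp.evap_coeff * vpd * (1 - f_int) * (sw / eff_cap)
        evap = min(evap, max(sw + prcp - runoff - uptake_mm, 0.0))
        sw = sw + prcp - runoff - uptake_mm - evap
        if sw > eff_cap:
            sw = eff_cap
        heat = min(1.0, max(0.0, 1 - (tmax - g.t_heat) / c.heat_span))
        rad = g.rue * f_int * srad * area * heat * 1.0 * drought
        wat = g.te * uptake / max(vpd, c.vpd_floor)
        gross = max(0.0, min(rad, wat))
        resp = c.m0 * (leaf + root + stem + grain) * c.q10 ** (((tmax + tmin) / 2 - 20) / 10)
        net = gross - resp
        if net >= 0:
            if stage == "veg":
                leaf += g.p_leaf * net
                root += g.p_root * net
                stem += (1 - g.p_leaf - g.p_root) * net
            else:
                grain += net
        else:
            deficit = -net
            d_stem = min(stem, deficit)
            stem -= d_stem
            leaf -= min(leaf, deficit - d_stem)
    return grain * m.density * 1e-6
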