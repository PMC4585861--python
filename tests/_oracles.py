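"""Independent literal-loop re-implementations of the annual accumulators.

Deliberately scalar and loop-based: each function walks one cell's 52-week
series with plain Python floats, mirroring the written definitions rather
than the vectorized implementation.
"""

WEEK_DAYS = [7.0] * 51 + [8.25]


def trapezoid(x, lo, a, b, hi):
    if x <= lo or x >= hi:
        return 0.0
    if a <= x <= b:
        return 1.0
    if x < a:
        return (x - lo) / (a - lo)
    return (hi - x) / (hi - b)


def annual_growth_index(ti_list, mi_list):
    acc = 0.0
    for ti, mi in zip(ti_list, mi_list):
        acc = acc + ti * mi
    return 100.0 * acc / 52.0


def degree_days(t_avg_list, dv0):
    return [max(0.0, t - dv0) * d for t, d in zip(t_avg_list, WEEK_DAYS)]


def cold_stress(t_min_list, dd_list, p):
    acc1 = 0.0
    for t in t_min_list:
        acc1 = acc1 + max(0.0, p.TTCS - t)
    acc2 = 0.0
    for dd in dd_list:
        acc2 = acc2 + max(0.0, p.DTCS - dd)
    cs1 = min(100.0, 100.0 * abs(p.THCS) * acc1)
    cs2 = min(100.0, 100.0 * abs(p.DHCS) * acc2)
    return min(100.0, max(cs1, cs2))


def heat_stress(t_max_list, p):
    acc = 0.0
    for t in t_max_list:
        acc = acc + max(0.0, t - p.TTHS)
    return min(100.0, 100.0 * p.THHS * acc)


def dry_stress(sm_list, p):
    acc = 0.0
    for sm in sm_list:
        acc = acc + max(0.0, p.SMDS - sm)
    return min(100.0, 100.0 * abs(p.HDS) * acc)


def wet_stress(sm_list, p):
    acc = 0.0
    for sm in sm_list:
        acc = acc + max(0.0, sm - p.SMWS)
    return min(100.0, 100.0 * p.HWS * acc)


def ecoclimatic_index(gia, cs, hs, ds, ws, annual_dd, p):
    if annual_dd < p.PDD:
        return 0.0
    ei = gia * (1 - cs / 100.0) * (1 - hs / 100.0) * (1 - ds / 100.0) * (1 - ws / 100.0)
    return min(100.0, max(0.0, ei))
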