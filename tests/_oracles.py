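"""Independent brute-force oracles for the test suite.

Deliberately written without reusing any perioprp classification logic:
explicit enumeration of site pairs and tooth pairs, and its own adjacency
table, so that agreement with the package is a genuine cross-check.
"""

from itertools import combinations

INTERPROX = {"MB", "DB", "ML", "DL"}
MID = {"B", "L"}

_UPPER = [17, 16, 15, 14, 13, 12, 11, 21, 22, 23, 24, 25, 26, 27]
_LOWER = [47, 46, 45, 44, 43, 42, 41, 31, 32, 33, 34, 35, 36, 37]


def brute_non_adjacent(a, b):
    for arch in (_UPPER, _LOWER):
        if a in arch and b in arch:
            return abs(arch.index(a) - arch.index(b)) > 1
    return True


def _measured(chart, selector, kinds):
    """List of (tooth, site, cal, ppd) over measured selected sites."""
    out = []
    for (fdi, site) in selector:
        if site not in kinds:
            continue
        tooth = chart.teeth[fdi]
        if not tooth.present or tooth.sites[site] is None:
            continue
        m = tooth.sites[site]
        out.append((fdi, site, m.cal_mm, m.ppd_mm))
    return out


def brute_stage_2012(chart, selector):
    """0/1/2/3 by explicit pair enumeration of the 2012 CDC/AAP rules."""
    sites = _measured(chart, selector, INTERPROX)

    def cal_at_least(th):
        return [(t, s) for t, s, cal, _ in sites if cal is not None and cal >= th]

    def ppd_at_least(th):
        return [(t, s) for t, s, _, ppd in sites if ppd is not None and ppd >= th]

    def pair_distinct_teeth(hits):
        return any(a[0] != b[0] for a, b in combinations(set(hits), 2))

    severe = (
        pair_distinct_teeth(cal_at_least(6)) and len(set(ppd_at_least(5))) >= 1
    )
    if severe:
        return 3
    moderate = pair_distinct_teeth(cal_at_least(4)) or pair_distinct_teeth(
        ppd_at_least(5)
    )
    if moderate:
        return 2
    mild = len(set(cal_at_least(3))) >= 2 and (
        pair_distinct_teeth(ppd_at_least(4)) or len(set(ppd_at_least(5))) >= 1
    )
    if mild:
        return 1
    return 0


def brute_stage_2018(chart, selector, detectable_cal=1):
    """0/1/2/3 by explicit enumeration of the 2018 EFP/AAP rules."""
    inter = _measured(chart, selector, INTERPROX)
    mid = _measured(chart, selector, MID)

    teeth_a = {t for t, _, cal, _ in inter if cal is not None and cal >= detectable_cal}
    case_a = any(
        brute_non_adjacent(t1, t2) for t1, t2 in combinations(sorted(teeth_a), 2)
    )
    teeth_b = {
        t
        for t, _, cal, ppd in mid
        if cal is not None and ppd is not None and cal >= 3 and ppd > 3
    }
    case_b = len(teeth_b) >= 2
    if not (case_a or case_b):
        return 0
    worst = max((cal for _, _, cal, _ in inter if cal is not None), default=0)
    if worst >= 5:
        return 3
    if worst >= 3:
        return 2
    return 1


def brute_pairwise_auc(reference, test):
    """Hand-Till style multiclass AUC via direct counting, independent of
    the package: for each class pair, each direction's hard-label AUC is
    P(hit|pos)/2 + P(correct rejection|neg)/2."""
    classes = sorted(set(reference))
    pair_values = []
    for i, j in combinations(classes, 2):
        idx = [k for k, r in enumerate(reference) if r in (i, j)]
        vals = []
        for pos in (i, j):
            npos = sum(1 for k in idx if reference[k] == pos)
            nneg = len(idx) - npos
            hit = sum(1 for k in idx if reference[k] == pos and test[k] == pos)
            rej = sum(1 for k in idx if reference[k] != pos and test[k] != pos)
            vals.append((hit / npos + rej / nneg) / 2)
        pair_values.append(sum(vals) / len(vals))
    return sum(pair_values) / len(pair_values)
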