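"""Independent hand-written oracles used by the test suite.

Everything here is deliberately re-derived from first principles (truth
tables, pair counting, exhaustive permutation enumeration) and shares no
code with the implementation it checks.
"""

from itertools import combinations

# --- trio genotype truth tables -------------------------------------------

HR, HT, HA = "hom_ref", "het", "hom_alt"
XR, XA = "hemi_ref", "hemi_alt"

# autosomal (proband, father, mother) -> site label
AUTOSOMAL_TABLE = {
    (HR, HR, HR): "uninformative",
    (HR, HR, HT): "uninformative",
    (HR, HR, HA): "uninformative",
    (HR, HT, HR): "uninformative",
    (HR, HT, HT): "uninformative",
    (HR, HT, HA): "uninformative",
    (HR, HA, HR): "uninformative",
    (HR, HA, HT): "uninformative",
    (HR, HA, HA): "uninformative",
    (HT, HR, HR): "de_novo",
    (HT, HR, HT): "inherited_maternal",
    (HT, HR, HA): "inherited_maternal",
    (HT, HT, HR): "inherited_paternal",
    (HT, HT, HT): "inherited_both",
    (HT, HT, HA): "inherited_both",
    (HT, HA, HR): "inherited_paternal",
    (HT, HA, HT): "inherited_both",
    (HT, HA, HA): "uninformative",  # both parents forced to transmit alt
    (HA, HR, HR): "uninformative",  # no parental alt source
    (HA, HR, HT): "uninformative",
    (HA, HR, HA): "uninformative",
    (HA, HT, HR): "uninformative",
    (HA, HT, HT): "inherited_both",
    (HA, HT, HA): "inherited_both",
    (HA, HA, HR): "uninformative",
    (HA, HA, HT): "inherited_both",
    (HA, HA, HA): "inherited_both",
}

# chrX, male proband: the father's X never reaches a son
X_MALE_TABLE = {}
for f in (XR, XA):
    for m in (HR, HT, HA):
        X_MALE_TABLE[(XR, f, m)] = "uninformative"
        X_MALE_TABLE[(XA, f, m)] = (
            "hemizygous_de_novo" if m == HR else "hemizygous_maternal"
        )

# chrX, female proband: the father always transmits his single X allele
X_FEMALE_TABLE = {
    (HR, XR, HR): "uninformative",
    (HR, XR, HT): "uninformative",
    (HR, XR, HA): "uninformative",
    (HR, XA, HR): "uninformative",
    (HR, XA, HT): "uninformative",
    (HR, XA, HA): "uninformative",
    (HT, XR, HR): "de_novo",
    (HT, XR, HT): "inherited_maternal",
    (HT, XR, HA): "inherited_maternal",
    (HT, XA, HR): "inherited_paternal",
    (HT, XA, HT): "inherited_both",
    (HT, XA, HA): "uninformative",  # must be hom_alt if father and mother transmit alt
    (HA, XR, HR): "uninformative",
    (HA, XR, HT): "uninformative",
    (HA, XR, HA): "uninformative",
    (HA, XA, HR): "uninformative",
    (HA, XA, HT): "inherited_both",
    (HA, XA, HA): "inherited_both",
}


# --- exact rank-sum enumeration -------------------------------------------


def u_statistic(a, b):
    return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)


def exact_ranksum_p(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of all C(n1+n2, n1)
    group assignments of the pooled values (valid without ties)."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(pooled)
    mu = n1 * len(y) / 2.0
    obs = abs(u_statistic(x, y) - mu)
    extreme = total = 0
    for idx in combinations(range(n), n1):
        chosen = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(n) if i not in chosen]
        total += 1
        if abs(u_statistic(a, b) - mu) >= obs - 1e-12:
            extreme += 1
    return extreme / total


# --- frequency-filter predicate -------------------------------------------


def filter_predicate(variant, threshold, mode):
    """One-line re-statement of the mode-conditional population filter."""
    het = max(a.het_af for a in variant.source_afs.values())
    hom = max(a.hom_count for a in variant.source_afs.values())
    hemi = max(a.hemi_count for a in variant.source_afs.values())
    return het < threshold and (
        (mode == "AD" and het == 0) or (mode in ("AR", "XL") and hom == 0 and hemi == 0)
    )
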