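"""5p/3p arm usage, arm-switching calls and Kolmogorov-Smirnov comparisons.

Arm usage of a miRNA is summarized two ways: the 5p fraction
f5 = c5 / (c5 + c3) and the pseudocounted log-ratio
log10((c5 + 0.5) / (c3 + 0.5)) — the pseudocount keeps zero-count arms
finite while dominance itself is decided on raw counts.  Between two
species, a miRNA has *switched* arms when the dominant arm differs; a
same-dominance difference larger than 10-fold in usage ratio is reported
as a within-band shift.  Distribution-level comparisons use the two-sample
KS statistic with the asymptotic p-value.

Records whose mature sequences are non-unique on both arms cannot be
attributed to a single locus and are excluded from species comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log10, sqrt

import numpy as np


@dataclass
class ArmCounts:
    mirna: str
    species: str
    c5: float
    c3: float
    unique5: bool = True
    unique3: bool = True
    family: str | None = None

    def __post_init__(self) -> None:
        if self.c5 < 0 or self.c3 < 0:
            raise ValueError("arm read counts must be non-negative")


@dataclass
class ArmUsageRecord:
    mirna: str
    species: str
    f5: float
    log_ratio: float
    dominant: str     # 5p | 3p | tie
    reliability: str  # both_unique | one_unique | excluded
    family: str | None = None


def arm_usage(counts: ArmCounts) -> ArmUsageRecord:
    """Per-miRNA usage summary; zero total reads is undefined."""
    total = counts.c5 + counts.c3
    if total <= 0:
        raise ValueError(f"{counts.mirna}: no reads on either arm")
    f5 = counts.c5 / total
    log_ratio = log10((counts.c5 + 0.5) / (counts.c3 + 0.5))
    dominant = ("5p" if counts.c5 > counts.c3
                else "3p" if counts.c3 > counts.c5 else "tie")
    reliability = ("both_unique" if counts.unique5 and counts.unique3
                   else "one_unique" if counts.unique5 or counts.unique3
                   else "excluded")
    return ArmUsageRecord(counts.mirna, counts.species, f5, log_ratio,
                          dominant, reliability, counts.family)


@dataclass
class FamilyArmUsage:
    family: str
    species: str
    f5: float
    log_ratio: float
    dominant: str
    n_members: int


def family_average(records: list[ArmUsageRecord]) -> FamilyArmUsage:
    """Mean of member f5 and log-ratio values (not pooled counts) for the
    multicopy families of one species; excluded members do not count."""
    usable = [r for r in records if r.reliability != "excluded"]
    if not usable:
        raise ValueError("family has no non-excluded members")
    species = usable[0].species
    family = usable[0].family or usable[0].mirna
    f5 = float(np.mean([r.f5 for r in usable]))
    lr = float(np.mean([r.log_ratio for r in usable]))
    dom = "5p" if f5 > 0.5 else "3p" if f5 < 0.5 else "tie"
    return FamilyArmUsage(family, species, f5, lr, dom, len(usable))


@dataclass
class SwitchCall:
    mirna: str
    species_pair: tuple[str, str]
    status: str  # conserved | switched | within_band_shift
    fold_change: float
    ambiguous: bool = False


def detect_arm_switch(rec_a, rec_b, fold_threshold: float = 10.0) -> SwitchCall:
    """Compare one miRNA/family between two species.

    ``switched``: dominant arms differ (the off-diagonal quadrants of a
    usage scatter).  ``within_band_shift``: same dominance but the usage
    ratios differ by more than ``fold_threshold``.  A dominance tie on one
    side is resolved from the sign of its log-ratio and flagged ambiguous.
    """
    if "excluded" in (getattr(rec_a, "reliability", "both_unique"),
                      getattr(rec_b, "reliability", "both_unique")):
        raise ValueError("excluded records cannot enter species comparisons")
    fold = 10.0 ** abs(rec_a.log_ratio - rec_b.log_ratio)
    ambiguous = "tie" in (rec_a.dominant, rec_b.dominant)

    def effective(rec) -> str:
        if rec.dominant != "tie":
            return rec.dominant
        return "5p" if rec.log_ratio >= 0 else "3p"

    if effective(rec_a) != effective(rec_b):
        status = "switched"
    elif fold > fold_threshold:
        status = "within_band_shift"
    else:
        status = "conserved"
    name = getattr(rec_a, "mirna", None) or getattr(rec_a, "family")
    return SwitchCall(name, (rec_a.species, rec_b.species), status, fold,
                      ambiguous)


@dataclass
class KsResult:
    D: float
    p: float
    n1: int
    n2: int


def _kolmogorov_sf(lam: float) -> float:
    """Q(lambda) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2)."""
    if lam <= 0:
        return 1.0
    total, k = 0.0, 1
    while True:
        term = 2.0 * (-1.0) ** (k - 1) * exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < 1e-12 or k > 1000:
            break
        k += 1
    return min(max(total, 0.0), 1.0)


def ks_two_sample(x, y) -> KsResult:
    """Two-sample KS test: D over pooled ECDF points, asymptotic p.

    D = sup |ECDF_x - ECDF_y| evaluated at the pooled sample points;
    p uses the Kolmogorov distribution at
    lambda = (sqrt(n_e) + 0.12 + 0.11 / sqrt(n_e)) * D with
    n_e = n1 n2 / (n1 + n2).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n1
    cdf_y = np.searchsorted(y, pooled, side="right") / n2
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    ne = n1 * n2 / (n1 + n2)
    lam = (sqrt(ne) + 0.12 + 0.11 / sqrt(ne)) * D
    return KsResult(D, _kolmogorov_sf(lam), n1, n2)


@dataclass
class SpeciesComparison:
    rows: list[tuple[str, float, float, str]]  # id, log_ratio A, B, status
    switches: list[SwitchCall]
    ks: KsResult


def compare_species(table_a: list[ArmUsageRecord | FamilyArmUsage],
                    table_b: list[ArmUsageRecord | FamilyArmUsage],
                    fold_threshold: float = 10.0) -> SpeciesComparison:
    """Pair records by family (falling back to the miRNA id), call arm
    switches per shared entry, and KS-compare the f5 distributions."""
    def key(rec) -> str:
        return getattr(rec, "family", None) or getattr(rec, "mirna", None) \
            or rec.family

    def usable(rec) -> bool:
        return getattr(rec, "reliability", "both_unique") != "excluded"

    a_by = {key(r): r for r in table_a if usable(r)}
    b_by = {key(r): r for r in table_b if usable(r)}
    shared = sorted(set(a_by) & set(b_by))
    if not shared:
        raise ValueError("no shared families between the two tables")
    rows, switches = [], []
    for k in shared:
        call = detect_arm_switch(a_by[k], b_by[k], fold_threshold)
        call.mirna = k
        rows.append((k, a_by[k].log_ratio, b_by[k].log_ratio, call.status))
        switches.append(call)
    ks = ks_two_sample([a_by[k].f5 for k in shared],
                       [b_by[k].f5 for k in shared])
    return SpeciesComparison(rows, switches, ks)
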