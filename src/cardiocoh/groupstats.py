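"""Nonparametric comparisons of band-coherence and rate statistics.

Group differences are assessed without distributional assumptions:
Kruskal-Wallis across more than two groups, followed — only when the
omnibus test is significant at alpha = 0.05 — by pairwise Wilcoxon rank-sum
tests.  No multiple-testing correction is applied; the number of tests
performed is recorded alongside the results so readers can judge the
look-elsewhere exposure themselves.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .coherence import BandStatistic, CoherenceSpectrum, band_mean, MODULATION_BAND

__all__ = [
    "GroupTestResult",
    "GenotypeTable",
    "collect_band_stats",
    "kruskal_wallis",
    "rank_sum",
    "genotype_comparison",
    "condition_comparison",
]

ALPHA = 0.05

GENOTYPE_VOCAB = {
    "NOTCH4": ("GG", "GA", "AA"),
    "CAT": ("CC", "CT", "TT"),
    "SOD2": ("CC", "CT", "TT"),
    "BDNF": ("GG", "GA", "AA"),
    "GPX1": ("CC", "CT", "TT"),
}


@dataclass(frozen=True)
class GroupTestResult:
    """Omnibus Kruskal-Wallis result with optional pairwise follow-up."""

    grouping: str  # "condition" or "genotype(<gene>)"
    groups: dict[str, np.ndarray]
    medians: dict[str, float]
    H: float
    p_kw: float
    pairwise: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)
    n_tests: int = 1  # omnibus + any pairwise tests actually run

    @property
    def significant(self) -> bool:
        return self.p_kw < ALPHA


@dataclass(frozen=True)
class GenotypeTable:
    """subject_id -> {gene -> genotype code}."""

    table: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for sid, genes in self.table.items():
            for gene, code in genes.items():
                vocab = GENOTYPE_VOCAB.get(gene)
                if vocab is not None and code not in vocab:
                    raise ValueError(f"{sid}: code {code!r} not in {gene} vocabulary {vocab}")

    def codes(self, gene: str) -> dict[str, str]:
        return {sid: genes[gene] for sid, genes in self.table.items() if gene in genes}

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenotypeTable":
        table: dict[str, dict[str, str]] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "subject\t")):
                    continue
                sid, gene, code = line.split("\t")
                table.setdefault(sid, {})[gene] = code
        return cls(table)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("subject\tgene\tcode\n")
            for sid in sorted(self.table):
                for gene in sorted(self.table[sid]):
                    fh.write(f"{sid}\t{gene}\t{self.table[sid][gene]}\n")


def collect_band_stats(
    results: dict[tuple[str, str], CoherenceSpectrum],
    band: tuple[float, float] = MODULATION_BAND,
) -> pd.DataFrame:
    """One row per subject x condition with its band-mean adjusted coherence.

    Missing recordings are simply absent rows (unbalanced designs are
    handled downstream by complete-case analysis per comparison).
    """
    rows = [
        BandStatistic(subject_id=sid, condition=cond,
                      value=band_mean(coh, *band), band=band)
        for (sid, cond), coh in sorted(results.items())
    ]
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "condition": [r.condition for r in rows],
            "value": [r.value for r in rows],
        }
    )


def kruskal_wallis(groups: dict[str, np.ndarray] | list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).

    All values identical across groups gives (0, 1) by convention.
    """
    values = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(values) < 2 or any(len(v) == 0 for v in values):
        raise ValueError("need >= 2 nonempty groups")
    flat = np.concatenate([np.asarray(v, float) for v in values])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    H, p = sstats.kruskal(*values)
    return float(H), float(p)


def rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic W of the first sample and the two-sided
    p-value: exact enumeration when the combined n <= 12 and there are no
    ties, otherwise the normal approximation with continuity and tie
    correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                              use_continuity=True)
    W = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum of x
    return W, float(res.pvalue)


def _omnibus_with_pairwise(grouping: str, groups: dict[str, np.ndarray]) -> GroupTestResult:
    H, p_kw = kruskal_wallis(groups)
    medians = {k: float(np.median(v)) for k, v in groups.items()}
    pairwise: list[tuple[tuple[str, str], float, float]] = []
    n_tests = 1
    if p_kw < ALPHA and len(groups) > 2:
        for a, b in itertools.combinations(sorted(groups), 2):
            W, p = rank_sum(groups[a], groups[b])
            pairwise.append(((a, b), W, p))
            n_tests += 1
    elif p_kw < ALPHA and len(groups) == 2:
        # the omnibus already is the two-group comparison; record the
        # rank-sum form of it for the report
        a, b = sorted(groups)
        W, p = rank_sum(groups[a], groups[b])
        pairwise.append(((a, b), W, p))
        n_tests += 1
    return GroupTestResult(
        grouping=grouping, groups=groups, medians=medians,
        H=H, p_kw=p_kw, pairwise=pairwise, n_tests=n_tests,
    )


def genotype_comparison(
    band_stats: pd.DataFrame, genotype_table: GenotypeTable, gene: str
) -> GroupTestResult:
    """Kruskal-Wallis of band coherence across genotype groups of one gene.

    ``band_stats`` must hold a single condition.  Genotype groups with no
    subjects are excluded with a warning; fewer than two remaining groups is
    an error (a single-genotype cohort cannot be compared).
    """
    conds = band_stats["condition"].unique()
    if len(conds) != 1:
        raise ValueError("genotype comparison expects band stats for exactly one condition")
    codes = genotype_table.codes(gene)
    missing = set(band_stats["subject_id"]) - set(codes)
    if missing:
        raise ValueError(f"genotype for {gene} missing for subjects {sorted(missing)}")
    groups: dict[str, np.ndarray] = {}
    for code in GENOTYPE_VOCAB.get(gene, sorted(set(codes.values()))):
        sel = band_stats["subject_id"].map(codes) == code
        vals = band_stats.loc[sel, "value"].to_numpy()
        if vals.size == 0:
            warnings.warn(f"{gene} group {code} empty in condition {conds[0]}; excluded",
                          stacklevel=2)
        else:
            groups[code] = vals
    if len(groups) < 2:
        raise ValueError(f"fewer than two non-empty {gene} genotype groups")
    return _omnibus_with_pairwise(f"genotype({gene})", groups)


def condition_comparison(stats: pd.DataFrame, value_col: str = "value") -> GroupTestResult:
    """Kruskal-Wallis of a per-subject statistic across exposure conditions.

    Pairwise rank-sum follow-up runs only when the omnibus is significant.
    """
    groups = {
        cond: sub[value_col].to_numpy()
        for cond, sub in stats.groupby("condition")
    }
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    return _omnibus_with_pairwise("condition", groups)
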