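"""Per-chimera sex-association testing and the bubble-plot table.

Each surviving chimera yields a 2x2 table of detected/not-detected by sex,
tested with Pearson's chi-squared (df = 1, no continuity correction):

    chi2 = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]

The headline significance flag uses the raw p against the -log10(0.05) = 1.3
cutoff, exactly as in the screen's bubble plot; Benjamini-Hochberg adjusted
values and a two-sided Fisher exact p (useful for zero cells) are reported
alongside but do not drive the flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .filters import ChimeraAggregate

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    """a/b: detected/not in females; c/d: detected/not in males."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_female(self) -> int:
        return self.a + self.b

    @property
    def n_male(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


class Chi2Result(NamedTuple):
    chi2: float
    p: float
    testable: bool


def sex_contingency(
    aggregate: ChimeraAggregate, n_female: int, n_male: int
) -> ContingencyTable:
    """Detection counts of one chimera against the cohort's sex totals."""
    a = aggregate.n_female_detected
    c = aggregate.n_male_detected
    if a > n_female or c > n_male:
        raise ValueError(
            f"detected counts ({a} F, {c} M) exceed cohort sizes ({n_female}, {n_male})"
        )
    return ContingencyTable(a=a, b=n_female - a, c=c, d=n_male - c)


def pearson_chi2(table: ContingencyTable) -> Chi2Result:
    """Pearson's chi-squared, df = 1, no continuity correction.

    Both row margins must be positive.  A zero *column* margin (a chimera
    detected in nobody, or in everybody) is flagged untestable rather than
    returning a number.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.n_female == 0 or table.n_male == 0:
        raise ValueError("both row margins (cohort sex totals) must be positive")
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return Chi2Result(math.nan, math.nan, testable=False)
    n = table.total
    chi2 = n * (a * d - b * c) ** 2 / (table.n_female * table.n_male * col1 * col2)
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return Chi2Result(float(chi2), p, testable=True)


def _chi2_observed_expected(table: ContingencyTable) -> float:
    """Equivalent Sum (O-E)^2 / E form; used as an internal cross-check."""
    obs = table.as_array().astype(float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (hypergeometric tail summation, margins fixed)."""
    if table.total == 0:
        raise ValueError("all cells zero")
    _, p = scipy.stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    if not p_values:
        return []
    _, adjusted, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(p) for p in adjusted]


@dataclass
class SexAssociationResult:
    chimera_key: tuple[str, str, int, int]
    table: ContingencyTable
    chi2: float
    p: float
    neg_log10_p: float
    pct_female: float
    total_detected: int
    significant: bool
    untestable: bool
    aggregate: ChimeraAggregate
    fisher_p: float | None = None
    p_adjusted: float | None = None


def sex_association(
    aggregates: list[ChimeraAggregate],
    n_female: int,
    n_male: int,
    alpha: float = DEFAULT_ALPHA,
) -> list[SexAssociationResult]:
    """Test every chimera for sex-biased detection."""
    cutoff = -math.log10(alpha)
    results: list[SexAssociationResult] = []
    for agg in aggregates:
        table = sex_contingency(agg, n_female, n_male)
        chi2, p, testable = pearson_chi2(table)
        total = table.a + table.c
        pct_female = 100.0 * table.a / total if total else math.nan
        if testable:
            neg_log10_p = -math.log10(p) if p > 0 else math.inf
            significant = neg_log10_p >= cutoff
            fisher_p = fisher_exact(table)
        else:
            neg_log10_p = math.nan
            significant = False
            fisher_p = None
        results.append(
            SexAssociationResult(
                chimera_key=agg.chimera_key,
                table=table,
                chi2=chi2,
                p=p,
                neg_log10_p=neg_log10_p,
                pct_female=pct_female,
                total_detected=total,
                significant=significant,
                untestable=not testable,
                aggregate=agg,
                fisher_p=fisher_p,
            )
        )
    testable_results = [r for r in results if not r.untestable]
    adjusted = bh_adjust([r.p for r in testable_results])
    for res, padj in zip(testable_results, adjusted):
        res.p_adjusted = padj
    return results


@dataclass(frozen=True)
class BubbleRow:
    x: int
    y: float
    size: int
    color: float
    label: str


def bubble_table(
    results: list[SexAssociationResult], alpha: float = DEFAULT_ALPHA
) -> tuple[list[BubbleRow], float]:
    """Bubble-plot rows (y = -log10 p, size = detections, color = % female).

    Rows are ordered by the genomic position of the representative 5'
    breakpoint and ranked along x.  Untestable chimeras are excluded with a
    logged count.  Returns (rows, cutoff_line) with the cutoff at
    -log10(alpha), i.e. 1.3 for alpha = 0.05.
    """
    cutoff = -math.log10(alpha)
    testable = [r for r in results if not r.untestable]
    skipped = len(results) - len(testable)
    if skipped:
        logger.info("bubble table: %d untestable chimeras excluded", skipped)

    def genomic_rank(res: SexAssociationResult):
        call = res.aggregate.representative.call
        return (call.chrom5, call.pos5, res.chimera_key)

    rows = [
        BubbleRow(
            x=rank,
            y=res.neg_log10_p,
            size=res.total_detected,
            color=res.pct_female,
            label=f"{res.chimera_key[0]}-{res.chimera_key[1]}",
        )
        for rank, res in enumerate(sorted(testable, key=genomic_rank), start=1)
    ]
    return rows, cutoff


def plot_bubble(rows: list[BubbleRow], cutoff: float, path) -> None:
    """Optional PNG/SVG render of the bubble table (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    if rows:
        xs = [r.x for r in rows]
        ys = [min(r.y, 300.0) for r in rows]
        sizes = [20 + 6 * r.size for r in rows]
        colors = [r.color for r in rows]
        sc = ax.scatter(xs, ys, s=sizes, c=colors, cmap="coolwarm", vmin=0, vmax=100, alpha=0.7)
        fig.colorbar(sc, ax=ax, label="% detected in females")
    ax.axhline(cutoff, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("chimeric RNAs (genomic rank of 5' breakpoint)")
    ax.set_ylabel("-log10 p (chi-squared)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
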