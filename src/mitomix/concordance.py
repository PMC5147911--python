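"""Call-set concordance: TP/FP/FN classification, recall/precision/F1, VAF
threshold grids, and combined mixture truth sets.

A test call matches a truth call only when both position and alternate allele
agree; a right-position/wrong-allele call therefore costs one FP and one FN.
Metrics with a zero denominator are reported as ``None`` (undefined), never
silently 0; F1 is 0 when TP = 0 but FP + FN > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pileup import CallSet, Pileup, call_snps
from .simdata import ReferenceGenome

Site = tuple[int, str]  # (0-based position, alt allele)


def metrics_from_counts(
    tp: int, fp: int, fn: int
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Recall, precision and F1 from confusion counts (None when undefined)."""
    recall = tp / (tp + fn) if tp + fn > 0 else None
    precision = tp / (tp + fp) if tp + fp > 0 else None
    if recall is None and precision is None:
        f1 = None
    elif tp == 0:
        f1 = 0.0 if fp + fn > 0 else None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return recall, precision, f1


@dataclass
class ConcordanceResult:
    tp_sites: set[Site]
    fp_sites: set[Site]
    fn_sites: set[Site]

    @property
    def tp(self) -> int:
        return len(self.tp_sites)

    @property
    def fp(self) -> int:
        return len(self.fp_sites)

    @property
    def fn(self) -> int:
        return len(self.fn_sites)

    @property
    def recall(self) -> Optional[float]:
        return metrics_from_counts(self.tp, self.fp, self.fn)[0]

    @property
    def precision(self) -> Optional[float]:
        return metrics_from_counts(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> Optional[float]:
        return metrics_from_counts(self.tp, self.fp, self.fn)[2]


def classify(test: CallSet, truth: CallSet) -> ConcordanceResult:
    """Partition sites into TP (both), FN (truth only), FP (test only)."""
    t, n = truth.sites, test.sites
    return ConcordanceResult(tp_sites=t & n, fp_sites=n - t, fn_sites=t - n)


def threshold_range(lo: float, hi: float, step: float) -> list[float]:
    """Inclusive VAF threshold grid, robust to float accumulation."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    if n <= 0:
        raise ValueError(f"range ({lo}, {hi}, {step}) yields no thresholds")
    return [round(lo + i * step, 10) for i in range(n)]


@dataclass
class GridResult:
    """M x N concordance matrix over (truth VAF, test VAF) threshold pairs."""

    truth_thresholds: list[float]
    test_thresholds: list[float]
    cells: list[list[ConcordanceResult]]
    truth_sets: list[CallSet] = field(default_factory=list, repr=False)
    test_sets: list[CallSet] = field(default_factory=list, repr=False)

    @property
    def argmax_cells(self) -> list[tuple[float, float]]:
        """All (truth VAF, test VAF) pairs attaining the maximum F1, in
        row-major order (truth ascending, then test ascending)."""
        best: Optional[float] = None
        for row in self.cells:
            for cell in row:
                if cell.f1 is not None and (best is None or cell.f1 > best):
                    best = cell.f1
        if best is None:
            return []
        return [
            (tt, nt)
            for i, tt in enumerate(self.truth_thresholds)
            for j, nt in enumerate(self.test_thresholds)
            if self.cells[i][j].f1 is not None
            and abs(self.cells[i][j].f1 - best) < 1e-12
        ]

    @property
    def max_f1(self) -> Optional[float]:
        f1s = [c.f1 for row in self.cells for c in row if c.f1 is not None]
        return max(f1s) if f1s else None

    def f1_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[c.f1 for c in row] for row in self.cells],
            index=pd.Index(self.truth_thresholds, name="truth_vaf"),
            columns=pd.Index(self.test_thresholds, name="test_vaf"),
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, tt in enumerate(self.truth_thresholds):
            for j, nt in enumerate(self.test_thresholds):
                c = self.cells[i][j]
                rows.append(
                    dict(
                        truth_vaf=tt, test_vaf=nt, tp=c.tp, fp=c.fp, fn=c.fn,
                        recall=c.recall, precision=c.precision, f1=c.f1,
                    )
                )
        return pd.DataFrame(rows)


def vaf_grid(
    test_pileup: Pileup,
    truth_pileup: Pileup,
    ref: ReferenceGenome,
    test_range: tuple[float, float, float] = (0.05, 0.95, 0.05),
    truth_range: tuple[float, float, float] = (0.05, 0.95, 0.05),
    mode: str = "single_source",
    min_depth: int = 20,
    truth_mode: Optional[str] = None,
) -> GridResult:
    """Call SNP subsets at every threshold of both axes and classify each
    (truth VAF, test VAF) pair, the truth-axis calls serving as ground truth.
    """
    truth_thresholds = threshold_range(*truth_range)
    test_thresholds = threshold_range(*test_range)
    truth_sets = [
        call_snps(truth_pileup, ref, t, min_depth=min_depth,
                  ploidy_mode=truth_mode or mode, platform="truth")
        for t in truth_thresholds
    ]
    test_sets = [
        call_snps(test_pileup, ref, t, min_depth=min_depth,
                  ploidy_mode=mode, platform="test")
        for t in test_thresholds
    ]
    cells = [[classify(n, m) for n in test_sets] for m in truth_sets]
    return GridResult(truth_thresholds, test_thresholds, cells, truth_sets, test_sets)


def grid_against_fixed_truth(
    test_pileup: Pileup,
    truth: CallSet,
    ref: ReferenceGenome,
    test_range: tuple[float, float, float],
    mode: str = "mixture",
    min_depth: int = 20,
) -> GridResult:
    """One-row grid: a fixed truth call set against a sweep of test VAFs."""
    test_thresholds = threshold_range(*test_range)
    test_sets = [
        call_snps(test_pileup, ref, t, min_depth=min_depth, ploidy_mode=mode,
                  platform="test")
        for t in test_thresholds
    ]
    cells = [[classify(n, truth) for n in test_sets]]
    return GridResult([truth.threshold], test_thresholds, cells, [truth], test_sets)


@dataclass
class CombinedTruthSet:
    """Union of two single-source call sets with sharing labels."""

    entries: dict[Site, str]  # site -> "shared" | "private:<label>"
    source_thresholds: tuple[float, float]

    @property
    def shared_sites(self) -> set[Site]:
        return {s for s, lab in self.entries.items() if lab == "shared"}

    def private_sites(self, label: Optional[str] = None) -> set[Site]:
        if label is None:
            return {s for s, lab in self.entries.items() if lab.startswith("private:")}
        return {s for s, lab in self.entries.items() if lab == f"private:{label}"}

    @property
    def n_shared(self) -> int:
        return len(self.shared_sites)

    @property
    def n_private(self) -> int:
        return len(self.private_sites())

    def as_call_set(self, a: CallSet, b: CallSet) -> CallSet:
        calls = {}
        for site in self.entries:
            calls[site] = a.calls.get(site) or b.calls[site]
        return CallSet(
            threshold=min(a.threshold, b.threshold), calls=calls,
            platform="combined", ploidy_mode="mixture",
        )


def combine_truth_sets(
    a: CallSet, b: CallSet, label_a: str = "A", label_b: str = "B"
) -> CombinedTruthSet:
    """Merge two single-source call sets keyed by (pos, alt).

    A site is shared iff present in both sets with the same alternate allele;
    otherwise private to its source.  Same position with different alternates
    yields two entries, each private.
    """
    entries: dict[Site, str] = {}
    for site in a.sites | b.sites:
        if site in a.sites and site in b.sites:
            entries[site] = "shared"
        elif site in a.sites:
            entries[site] = f"private:{label_a}"
        else:
            entries[site] = f"private:{label_b}"
    return CombinedTruthSet(entries, (a.threshold, b.threshold))


def round_metric(value: Optional[float], places: int = 3) -> Optional[float]:
    """Report a metric at 3 decimals, round-half-even (banker's)."""
    if value is None:
        return None
    return float(np.round(value, places))


def plot_f1_heatmap(grid: GridResult, path, title: str = "F1 by VAF threshold"):
    """Render the grid's F1 matrix as a heatmap image (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = grid.f1_matrix().to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(matrix, origin="lower", aspect="auto", vmin=0, vmax=1,
                   cmap="Blues")
    ax.set_xticks(range(len(grid.test_thresholds)))
    ax.set_xticklabels([f"{t:.2f}" for t in grid.test_thresholds], rotation=90,
                       fontsize=7)
    ax.set_yticks(range(len(grid.truth_thresholds)))
    ax.set_yticklabels([f"{t:.2f}" for t in grid.truth_thresholds], fontsize=7)
    ax.set_xlabel("test VAF")
    ax.set_ylabel("truth VAF")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="F1")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
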