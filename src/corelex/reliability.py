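"""Inter-method reliability: two-way random absolute-agreement ICC, bands,
item-level discrepancy audit and error proportions.

The intraclass correlation used here is ICC(2,1) in the Shrout–Fleiss
taxonomy (ICC(A,1) in McGraw–Wong): samples and scoring methods are both
random effects and systematic offsets between methods count against
agreement.  From the two-way ANOVA mean squares (rows = samples, columns =
methods),

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with the 95% confidence interval from the F-based method for this model.
Average-measures ICC(2,k) is available behind a flag, since a validation
design in which each transcript is scored once per modality reports single
measures.  Bands: poor < .5 <= moderate < .75 <= good < .9 <= excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist

from .errors import ModalityMismatchError
from .scoring import ScoreTable

_EPS = 1e-12


@dataclass
class RatingsMatrix:
    """n samples x k methods table of checklist totals."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    method_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D samples x methods table")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >=2 samples and >=2 methods, got {n}x{k}")
        if not np.isfinite(self.values).all():
            raise ValueError("ratings matrix contains missing cells")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if not self.method_labels:
            self.method_labels = [f"m{j}" for j in range(k)]

    @classmethod
    def from_score_tables(cls, a: ScoreTable, b: ScoreTable,
                          labels: tuple[str, str] = ("A", "B")
                          ) -> "RatingsMatrix":
        _check_comparable(a, b)
        bmap = {r.sample_id: r.total for r in b.rows}
        values = np.array([[r.total, bmap[r.sample_id]] for r in a.rows],
                          dtype=float)
        return cls(values=values, sample_ids=[r.sample_id for r in a.rows],
                   method_labels=list(labels))


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-9 <= self.icc <= self.ci_high + 1e-9):
            raise ValueError("CI does not bracket the point estimate")


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way_random_agreement(m: RatingsMatrix, average: bool = False,
                                 alpha: float = 0.05) -> ICCResult:
    """ICC for a two-way random model with absolute agreement.

    ``average=False`` (default) gives single measures, ICC(2,1);
    ``average=True`` gives average measures, ICC(2,k).  A matrix with zero
    total variance (all cells equal) is perfect agreement by convention:
    the ICC is 1 with a degenerate CI and the result is flagged.
    """
    x = m.values
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    model = ("two-way random, absolute agreement, "
             + ("average measures" if average else "single measures"))

    if np.ptp(x) < _EPS:  # all cells identical
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0, model=model,
                         ms_rows=msr, ms_cols=msc, ms_error=mse,
                         n=n, k=k, degenerate=True)

    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    icc1 = (msr - mse) / denom_single
    if mse < _EPS and msc < _EPS:
        # Perfect agreement with real between-sample variance: the F-based
        # interval collapses.
        icc = 1.0
        return ICCResult(icc=icc, ci_low=1.0, ci_high=1.0, model=model,
                         ms_rows=msr, ms_cols=msc, ms_error=mse,
                         n=n, k=k, degenerate=True)

    # McGraw & Wong F-based CI for ICC(A,1).
    r = icc1
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num = (a * msc + b * mse) ** 2
        den = ((a * msc) ** 2 / (k - 1)
               + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        v = num / den if den > 0 else (n - 1) * (k - 1)
        f_l = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_u = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_l * mse)
              / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_u * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    else:  # pragma: no cover - unreachable when mse or msc > 0
        lo = hi = 1.0

    if average:
        icc_k = (msr - mse) / (msr + (msc - mse) / n)
        lo = lo * k / (1 + (k - 1) * lo)
        hi = hi * k / (1 + (k - 1) * hi)
        return ICCResult(icc=float(icc_k), ci_low=float(min(lo, icc_k)),
                         ci_high=float(max(hi, icc_k)), model=model,
                         ms_rows=msr, ms_cols=msc, ms_error=mse, n=n, k=k)
    return ICCResult(icc=float(icc1), ci_low=float(min(lo, icc1)),
                     ci_high=float(max(hi, icc1)), model=model,
                     ms_rows=msr, ms_cols=msc, ms_error=mse, n=n, k=k)


_BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))


def interpret_icc(value: float) -> str:
    """Reliability band: poor < .5 <= moderate < .75 <= good < .9 <= excellent."""
    if value > 1:
        raise ValueError("ICC cannot exceed 1")
    for cut, label in _BANDS:
        if value >= cut:
            return label
    return "poor"


@dataclass(frozen=True)
class Discrepancy:
    sample_id: str
    item: str
    a_value: int
    b_value: int

    @property
    def direction(self) -> str:
        """'a_only' when method A credited the item and B did not."""
        return "a_only" if self.a_value > self.b_value else "b_only"


@dataclass
class DiscrepancyReport:
    entries: list[Discrepancy]
    n_samples: int
    n_items: int

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def counts(self) -> dict[str, int]:
        out = {"a_only": 0, "b_only": 0}
        for e in self.entries:
            out[e.direction] += 1
        return out

    @property
    def proportion(self) -> float:
        return error_proportion(len(self.entries), self.n_items,
                                self.n_samples)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame.from_records(
            [{"sample_id": e.sample_id, "item": e.item,
              "a_value": e.a_value, "b_value": e.b_value,
              "direction": e.direction} for e in self.entries],
            columns=["sample_id", "item", "a_value", "b_value", "direction"])


def _check_comparable(a: ScoreTable, b: ScoreTable) -> None:
    if sorted(r.sample_id for r in a.rows) != sorted(r.sample_id for r in b.rows):
        raise ModalityMismatchError("sample ids differ between the two tables")
    tasks = {r.task_id for r in a.rows} | {r.task_id for r in b.rows}
    if len(tasks) > 1:
        raise ModalityMismatchError(f"tables mix tasks: {sorted(tasks)}")
    hashes = {r.lexicon_hash for r in a.rows if r.lexicon_hash} \
        | {r.lexicon_hash for r in b.rows if r.lexicon_hash}
    if len(hashes) > 1:
        raise ModalityMismatchError(
            f"tables were scored against different checklist versions: "
            f"{sorted(hashes)}")


def compare_modalities(a: ScoreTable, b: ScoreTable) -> DiscrepancyReport:
    """Item-by-item audit of two scorings of the same samples.

    Lists every (sample, item) cell where the two modalities disagree, with
    the direction of the disagreement.  Empty iff the tables are identical.
    """
    _check_comparable(a, b)
    bmap = {r.sample_id: r for r in b.rows}
    entries: list[Discrepancy] = []
    n_items = 0
    for ra in a.rows:
        rb = bmap[ra.sample_id]
        if set(ra.per_item) != set(rb.per_item):
            raise ModalityMismatchError(
                f"sample {ra.sample_id}: item sets differ between tables")
        n_items = len(ra.per_item)
        for item, av in ra.per_item.items():
            bv = rb.per_item[item]
            if av != bv:
                entries.append(Discrepancy(sample_id=ra.sample_id, item=item,
                                           a_value=av, b_value=bv))
    return DiscrepancyReport(entries=entries, n_samples=len(a.rows),
                             n_items=n_items)


def error_proportion(n_errors: int, n_items: int, n_samples: int) -> float:
    """Errors over total scoring opportunities: n_errors / (n_items * n_samples)."""
    if min(n_errors, n_items, n_samples) < 0:
        raise ValueError("counts must be non-negative")
    if n_items * n_samples == 0:
        raise ZeroDivisionError("n_items * n_samples must be positive")
    return n_errors / (n_items * n_samples)
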