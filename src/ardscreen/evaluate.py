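"""Diagnostic-accuracy statistics versus expert adjudication.

Confusion matrices against the three-class adjudication label,
sensitivity / specificity / PPV / NPV / accuracy with binomial intervals
(Wilson by default, Clopper–Pearson optional), Cohen's κ for the three
categories, the finite-population margin of error that sizes a review
sample, per-window PPV gradients, and 2×2 odds ratios.

Handling of the intermediate "possible ARDS" label is explicit: the default
excludes POSSIBLE stays from 2×2 computations; ``AS_NEGATIVE`` counts them
with the negatives; ``ARDS_OR_POSSIBLE`` widens the positive definition
instead. Undefined metrics (zero margin) are reported as None, never 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .ehr_model import Label


class PositiveDefinition(str, enum.Enum):
    ARDS_ONLY = "ARDS_ONLY"
    ARDS_OR_POSSIBLE = "ARDS_OR_POSSIBLE"


class PossibleHandling(str, enum.Enum):
    AS_NEGATIVE = "AS_NEGATIVE"
    EXCLUDE = "EXCLUDE"


@dataclass(frozen=True)
class Confusion2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class LabelMismatchError(ValueError):
    """Flagged stays lack an adjudication label."""


def confusion(
    labels: pd.DataFrame,
    flags: Mapping[str, bool] | pd.Series,
    positive_definition: PositiveDefinition | str = PositiveDefinition.ARDS_ONLY,
    possible_handling: PossibleHandling | str = PossibleHandling.EXCLUDE,
) -> Confusion2x2:
    """Tally a 2×2 confusion matrix of a binary flag against adjudication.

    ``labels`` has columns ``stay_id, label``; ``flags`` maps stay_id to a
    boolean (stays absent from ``flags`` count as unflagged). Every *flagged*
    stay must be labelled.
    """
    positive_definition = PositiveDefinition(positive_definition)
    possible_handling = PossibleHandling(possible_handling)
    if isinstance(flags, pd.Series):
        flags = flags.to_dict()

    labelled = set(labels["stay_id"])
    unlabelled = sorted(s for s, f in flags.items() if f and s not in labelled)
    if unlabelled:
        raise LabelMismatchError(f"flagged stay(s) without adjudication label: {unlabelled}")

    df = labels.copy()
    df["flag"] = df["stay_id"].map(lambda s: bool(flags.get(s, False)))
    if positive_definition is PositiveDefinition.ARDS_OR_POSSIBLE:
        pos = df["label"].isin([Label.ARDS.value, Label.POSSIBLE.value])
    else:
        if possible_handling is PossibleHandling.EXCLUDE:
            df = df[df["label"] != Label.POSSIBLE.value]
        pos = df["label"] == Label.ARDS.value
    pos = pos.loc[df.index]
    return Confusion2x2(
        tp=int((pos & df["flag"]).sum()),
        fp=int((~pos & df["flag"]).sum()),
        fn=int((pos & ~df["flag"]).sum()),
        tn=int((~pos & ~df["flag"]).sum()),
    )


# ---------------------------------------------------------------------------
# binomial intervals

def wilson_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    lo, hi = proportion_confint(x, n, alpha=1 - conf, method="wilson")
    # the score interval's endpoints are exactly 0/1 at the boundary counts;
    # snap away numerical noise so the interval always contains x/n
    return float(0.0 if x == 0 else max(0.0, lo)), float(1.0 if x == n else min(1.0, hi))


def clopper_pearson_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) interval via Beta quantiles."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    lo, hi = proportion_confint(x, n, alpha=1 - conf, method="beta")
    return float(0.0 if x == 0 else lo), float(1.0 if x == n else hi)


_CI_METHODS = {"wilson": wilson_ci, "clopper-pearson": clopper_pearson_ci}


@dataclass(frozen=True)
class MetricCI:
    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class DxMetrics:
    sensitivity: Optional[MetricCI]
    specificity: Optional[MetricCI]
    ppv: Optional[MetricCI]
    npv: Optional[MetricCI]
    accuracy: Optional[MetricCI]

    def to_dict(self) -> dict:
        return asdict(self)


def dx_metrics(c: Confusion2x2, ci_method: str = "wilson", conf: float = 0.95) -> DxMetrics:
    """Accuracy measures from a 2×2 table, with per-metric binomial CIs.

    A metric whose margin is zero is undefined (None), not 0.
    """
    ci = _CI_METHODS[ci_method]

    def prop(x: int, n: int) -> Optional[MetricCI]:
        if n == 0:
            return None
        lo, hi = ci(x, n, conf)
        return MetricCI(x / n, lo, hi)

    return DxMetrics(
        sensitivity=prop(c.tp, c.tp + c.fn),
        specificity=prop(c.tn, c.tn + c.fp),
        ppv=prop(c.tp, c.tp + c.fp),
        npv=prop(c.tn, c.tn + c.fn),
        accuracy=prop(c.tp + c.tn, c.total) if c.total else None,
    )


# ---------------------------------------------------------------------------
# agreement, precision, association

@dataclass(frozen=True)
class KappaResult:
    p_o: float
    p_e: float
    kappa: Optional[float]


def cohen_kappa(table: np.ndarray | Sequence[Sequence[float]]) -> KappaResult:
    """Cohen's κ from a square inter-observer agreement table.

    ``p_o`` is the observed agreement (trace / total), ``p_e`` the chance
    agreement from the margins; κ = (p_o − p_e) / (1 − p_e), undefined when
    p_e = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    total = t.sum()
    if total <= 0:
        raise ValueError("agreement table must have positive total")
    p_o = np.trace(t) / total
    p_e = float(np.sum(t.sum(axis=1) * t.sum(axis=0)) / total**2)
    kappa = None if math.isclose(p_e, 1.0) else (p_o - p_e) / (1 - p_e)
    return KappaResult(p_o=float(p_o), p_e=p_e, kappa=kappa)


def fpc_margin(p: float, n: int, N: int, conf: float = 0.95) -> float:
    """Margin of error for a proportion with finite-population correction.

    ``z · sqrt(p(1−p)/n) · sqrt((N−n)/(N−1))`` — the half-width used to size
    a review sample drawn without replacement from a finite screen-positive
    population of size N.
    """
    if not 0 < n <= N:
        raise ValueError("need 0 < n <= N")
    z = stats.norm.ppf((1 + conf) / 2)
    fpc = math.sqrt((N - n) / (N - 1)) if N > 1 else 0.0
    return float(z * math.sqrt(p * (1 - p) / n) * fpc)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool


def odds_ratio_2x2(a: int, b: int, c: int, d: int, conf: float = 0.95) -> OddsRatioResult:
    """Sample odds ratio (a·d)/(b·c) with a log-scale Wald interval.

    When any cell is zero, the Haldane–Anscombe correction (add 0.5 to every
    cell) is applied and flagged.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    haldane = bool(np.any(cells == 0))
    if haldane:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(sum(1 / x for x in cells))
    z = stats.norm.ppf((1 + conf) / 2)
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(math.exp(math.log(or_) - z * se)),
        ci_high=float(math.exp(math.log(or_) + z * se)),
        haldane_corrected=haldane,
    )


# ---------------------------------------------------------------------------
# PPV gradient across persistence windows

PPV_WINDOWS = ("anytime", "24", "48", "72")


def ppv_gradient(
    labels_by_window: Mapping[str, Sequence[str]],
    ci_method: str = "wilson",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Diagnostic yield per persistence window from reviewed samples.

    ``labels_by_window`` maps a window name to the adjudication labels of its
    reviewed sample. Returns one row per window with counts, PPV (definite
    ARDS), PPV including possible ARDS, and CIs for both.
    """
    ci = _CI_METHODS[ci_method]
    rows = []
    for window, lbls in labels_by_window.items():
        lbls = list(lbls)
        n = len(lbls)
        n_ards = sum(1 for l in lbls if l == Label.ARDS.value)
        n_poss = sum(1 for l in lbls if l == Label.POSSIBLE.value)
        n_non = n - n_ards - n_poss
        row: dict = {"window": window, "n_reviewed": n, "n_ards": n_ards,
                     "n_possible": n_poss, "n_non": n_non}
        if n:
            lo, hi = ci(n_ards, n, conf)
            row.update(ppv=n_ards / n, ppv_ci_low=lo, ppv_ci_high=hi)
            lo, hi = ci(n_ards + n_poss, n, conf)
            row.update(ppv_with_possible=(n_ards + n_poss) / n,
                       ppv_wp_ci_low=lo, ppv_wp_ci_high=hi)
        else:
            row.update(ppv=None, ppv_ci_low=None, ppv_ci_high=None,
                       ppv_with_possible=None, ppv_wp_ci_low=None, ppv_wp_ci_high=None)
        rows.append(row)
    return pd.DataFrame(rows)


def sample_reviews(
    screen_results: pd.DataFrame,
    labels: pd.DataFrame,
    n_per_window: Mapping[str, int],
    seed: int,
) -> dict[str, list[str]]:
    """Draw seeded review samples from each screening cohort.

    Mirrors a chart-review design: for each named window, sample up to
    ``n_per_window[window]`` labelled screen-positive stays without
    replacement and return their labels. Requires labels for the whole
    screened population.
    """
    from .screen import in_window

    label_of = dict(zip(labels["stay_id"], labels["label"]))
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for window, n in n_per_window.items():
        pool = screen_results.loc[in_window(screen_results, window), "stay_id"]
        pool = [s for s in pool if s in label_of]
        take = min(n, len(pool))
        chosen = rng.choice(np.array(pool, dtype=object), size=take, replace=False) if take else []
        out[window] = [label_of[s] for s in chosen]
    return out


def round_half_away(x: float, digits: int = 0) -> float:
    """Round half away from zero (report-style rounding, not banker's)."""
    factor = 10**digits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
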