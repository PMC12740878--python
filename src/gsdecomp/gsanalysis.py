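"""Unique contributions of SLFOs and EEG band power to the global signal.

The contribution of each regressor to a subject's global signal is the
partial Pearson correlation controlling for all other regressors.  Chance
levels come from inter-subject surrogates: subject i's global signal paired
with subject j's regressors (j != i, ordered pairs), which preserves the
autocorrelation of both sides while destroying any true coupling.  Observed
and surrogate distributions are compared with a two-sided Wilcoxon
rank-sum test; band p-values are Benjamini-Hochberg corrected across the
four EEG bands only (the SLFO test stands alone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSignalError, InputError

__all__ = [
    "SubjectSignals",
    "partial_correlation",
    "observed_contributions",
    "surrogate_contributions",
    "contribution_test",
    "full_model_fit",
    "regressor_correlation",
    "BAND_NAMES",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta")


@dataclass
class SubjectSignals:
    """Censor-aligned per-subject series entering the group analysis."""

    subject_id: str
    gs: np.ndarray
    regressors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gs = np.asarray(self.gs, dtype=float)
        self.regressors = {
            k: np.asarray(v, dtype=float) for k, v in self.regressors.items()
        }
        for k, v in self.regressors.items():
            if v.size != self.gs.size:
                raise InputError(
                    f"regressor {k!r} length {v.size} != gs length {self.gs.size}"
                )


def _residualise(y: np.ndarray, controls: np.ndarray | None) -> np.ndarray:
    if controls is None or controls.size == 0:
        return y - y.mean()
    design = np.column_stack([np.ones(y.size), controls])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InputError("control regressors are rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation(
    gs: np.ndarray, x: np.ndarray, controls: list[np.ndarray] | None = None
) -> float:
    """Pearson correlation of ``gs`` and ``x`` after regressing out controls.

    An empty control set reduces to the plain Pearson correlation; ``x``
    lying in the span of the controls is degenerate.
    """
    gs = np.asarray(gs, dtype=float)
    x = np.asarray(x, dtype=float)
    if gs.size != x.size:
        raise InputError("series lengths differ")
    c = None
    if controls:
        c = np.column_stack([np.asarray(ci, dtype=float) for ci in controls])
        if c.shape[0] != gs.size:
            raise InputError("control length does not match series length")
    rg = _residualise(gs, c)
    rx = _residualise(x, c)
    if rx.std() < 1e-10 * max(1.0, np.abs(x).max()):
        raise DegenerateSignalError("x lies in the span of the controls")
    if rg.std() < 1e-12:
        raise DegenerateSignalError("gs lies in the span of the controls")
    return float(np.corrcoef(rg, rx)[0, 1])


def _contribution(signals: SubjectSignals, name: str,
                  gs: np.ndarray | None = None) -> float:
    if name not in signals.regressors:
        raise InputError(f"subject {signals.subject_id} lacks regressor {name!r}")
    n = (gs if gs is not None else signals.gs).size
    x = signals.regressors[name][:n]
    controls = [v[:n] for k, v in signals.regressors.items() if k != name]
    return partial_correlation(
        (signals.gs if gs is None else gs)[:n], x, controls
    )


def observed_contributions(
    subjects: list[SubjectSignals], name: str
) -> np.ndarray:
    """Per-subject partial correlation of ``name`` with that subject's gs."""
    return np.array([_contribution(s, name) for s in subjects])


def surrogate_contributions(
    subjects: list[SubjectSignals], name: str
) -> np.ndarray:
    """Inter-subject surrogate null distribution of the partial correlation.

    For every ordered pair (i, j), i != j, subject i's global signal is
    paired with subject j's regressors (the controls also come from subject
    j); both sides are truncated to the shorter censored length.  Fully
    deterministic - no random number generation is involved.
    """
    if len(subjects) < 2:
        raise InputError("surrogates require at least 2 subjects")
    out = []
    for i, si in enumerate(subjects):
        for j, sj in enumerate(subjects):
            if i == j:
                continue
            n = min(si.gs.size, sj.gs.size)
            out.append(_contribution(sj, name, gs=si.gs[:n]))
    return np.array(out)


def contribution_test(
    observed: dict[str, np.ndarray],
    null: dict[str, np.ndarray],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum test of observed vs surrogate contributions, per regressor.

    Returns one row per regressor with the observed group mean/SD, the raw
    two-sided p-value and, for the four EEG bands only, the BH-FDR adjusted
    p-value (the SLFO p-value is reported uncorrected).
    """
    rows = []
    for name in observed:
        obs = np.asarray(observed[name], dtype=float)
        nul = np.asarray(null[name], dtype=float)
        if obs.size == 0 or nul.size == 0:
            raise InputError(f"empty sample for regressor {name!r}")
        p = float(stats.ranksums(obs, nul).pvalue)
        rows.append({
            "regressor": name,
            "mean_r": float(obs.mean()),
            "sd_r": float(obs.std(ddof=1)) if obs.size > 1 else np.nan,
            "p_value": p,
        })
    df = pd.DataFrame(rows).set_index("regressor")
    df["p_fdr"] = df["p_value"]
    band_idx = [b for b in BAND_NAMES if b in df.index]
    if band_idx:
        _, p_adj, _, _ = multipletests(
            df.loc[band_idx, "p_value"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        df.loc[band_idx, "p_fdr"] = p_adj
    df["significant"] = df["p_fdr"] < alpha
    return df.reset_index()


def full_model_fit(
    gs: np.ndarray, slfo: np.ndarray, bands: list[np.ndarray]
) -> float:
    """Multiple correlation of gs with its OLS fit on [slfo, bands]."""
    gs = np.asarray(gs, dtype=float)
    design = np.column_stack(
        [np.ones(gs.size), np.asarray(slfo, dtype=float)]
        + [np.asarray(b, dtype=float) for b in bands]
    )
    if design.shape[0] != gs.size:
        raise InputError("regressor length does not match gs")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InputError("full-model design is rank deficient")
    beta, *_ = np.linalg.lstsq(design, gs, rcond=None)
    fit = design @ beta
    if fit.std() < 1e-12:
        raise DegenerateSignalError("fitted series is constant")
    return float(np.corrcoef(gs, fit)[0, 1])


def regressor_correlation(
    x: np.ndarray, y: np.ndarray, gs: np.ndarray | None = None
) -> tuple[float, float]:
    """Correlation between two regressors, plain or controlling for gs.

    Returns ``(r, p)`` from a Pearson test; if ``gs`` is given both series
    are residualised on it first (partial correlation given the global
    signal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if gs is not None:
        c = np.asarray(gs, dtype=float)[:, None]
        x = _residualise(x, c)
        y = _residualise(y, c)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
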