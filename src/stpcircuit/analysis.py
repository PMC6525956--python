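"""Firing-rate, direction-decision and spike-count-correlation analyses.

Rates are spike counts over a half-open window divided by its length
(spikes/s); an onset-skip window such as (280, 1280) discards the initial
transient the way evoked-response analyses commonly do. The direction
decision compares the two subpopulations' mean rates -- the in-silico
analogue of lighting the red (right) or blue (left) LED. Spike-count
correlations (SCC) are Pearson coefficients between units' spike counts in
nonoverlapping 1-ms bins, concatenated across stimulus presentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RateSummary",
    "SCCMatrix",
    "firing_rate",
    "rate_summary",
    "decide_direction",
    "step_decisions",
    "experiment_rate_table",
    "bin_counts",
    "binned_counts",
    "scc_matrix",
    "experiment_scc",
]


@dataclass
class RateSummary:
    """Per-unit and per-subpopulation firing rates over one window.

    ``per_unit_rate`` is in spikes/s; ``per_subpop_rate`` maps subpopulation
    label (1, 2) to the arithmetic mean rate of its member units;
    ``window`` is the (start_ms, end_ms) interval used.
    """

    per_unit_rate: np.ndarray
    per_subpop_rate: dict
    window: tuple


def firing_rate(trains, window) -> np.ndarray:
    """Per-unit firing rates (spikes/s) in the half-open window [start, end).

    ``trains`` is a sequence of per-unit spike-time arrays in ms.
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    length_s = (end - start) / 1000.0
    return np.array(
        [np.count_nonzero((np.asarray(t) >= start) & (np.asarray(t) < end)) / length_s
         for t in trains]
    )


def rate_summary(trains, labels, window) -> RateSummary:
    """Rates plus subpopulation means for one set of spike trains."""
    labels = np.asarray(labels)
    rates = firing_rate(trains, window)
    per_subpop = {
        int(lab): float(rates[labels == lab].mean()) for lab in np.unique(labels)
    }
    return RateSummary(per_unit_rate=rates, per_subpop_rate=per_subpop,
                       window=(float(window[0]), float(window[1])))


def decide_direction(rates: RateSummary) -> str:
    """LED-style decision from subpopulation mean rates.

    Returns ``"right"`` if subpopulation 1 out-fires subpopulation 2,
    ``"left"`` if the reverse, ``"undecided"`` on an exact tie.
    """
    r1 = rates.per_subpop_rate.get(1, 0.0)
    r2 = rates.per_subpop_rate.get(2, 0.0)
    if r1 > r2:
        return "right"
    if r2 > r1:
        return "left"
    return "undecided"


def step_decisions(results, labels, window=None) -> list:
    """Per-step direction decisions over a list of SimulationResults."""
    out = []
    for res in results:
        win = window if window is not None else (0.0, float(res.times[-1] + 1))
        out.append(decide_direction(rate_summary(res.raster, labels, win)))
    return out


def experiment_rate_table(results, labels, window=None) -> pd.DataFrame:
    """Long-format per-step rate table for a simulated direction sweep.

    One row per (step, unit) with columns ``step``, ``direction``, ``unit``,
    ``subpop`` and ``rate`` (spikes/s), ready for groupby summaries.
    """
    labels = np.asarray(labels)
    rows = []
    for res in results:
        win = window if window is not None else (0.0, float(res.times[-1] + 1))
        rates = firing_rate(res.raster, win)
        for unit, rate in enumerate(rates):
            rows.append(
                {"step": res.step_index, "direction": res.direction,
                 "unit": unit, "subpop": int(labels[unit]), "rate": rate}
            )
    return pd.DataFrame(rows)


def bin_counts(train, T: float, bin_width: float = 1.0) -> np.ndarray:
    """Spike counts of one train in nonoverlapping bins tiling [0, T).

    ``bin_width`` must divide ``T`` exactly; spikes fall into half-open bins
    ``[k * w, (k + 1) * w)`` so the series total equals the train length.
    """
    n_bins = T / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide T")
    n_bins = int(round(n_bins))
    t = np.asarray(train, dtype=float)
    if t.size and (t.min() < 0 or t.max() >= T):
        raise ValueError("spike times must lie in [0, T)")
    idx = np.floor(t / bin_width).astype(int)
    return np.bincount(idx, minlength=n_bins).astype(float)


def binned_counts(trains, T: float, bin_width: float = 1.0) -> np.ndarray:
    """Stacked (n_units, n_bins) count series for a set of trains."""
    return np.stack([bin_counts(t, T, bin_width) for t in trains])


@dataclass
class SCCMatrix:
    """Pairwise spike-count correlations with subpopulation means.

    ``r`` is the N x N Pearson matrix of the binned count series (NaN for
    pairs involving a zero-variance series); ``mean_within`` and
    ``mean_between`` average the off-diagonal entries over same-label and
    different-label pairs respectively, excluding flagged zero-variance
    pairs (listed in ``excluded_pairs``).
    """

    r: np.ndarray
    bin_width: float
    mean_within: float
    mean_between: float
    excluded_pairs: list


def scc_matrix(counts, labels, bin_width: float = 1.0) -> SCCMatrix:
    """Pearson correlation matrix of binned spike-count series.

    ``counts`` is (n_units, n_bins); units with zero-variance series yield
    undefined correlations -- those pairs are excluded from the within /
    between means and reported in ``excluded_pairs``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need at least two equal-length count series")
    labels = np.asarray(labels)
    if labels.shape != (counts.shape[0],):
        raise ValueError("labels must give one subpopulation per series")
    n = counts.shape[0]
    variances = counts.var(axis=1)
    silent = variances == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(counts)
    r[silent, :] = np.nan
    r[:, silent] = np.nan
    np.fill_diagonal(r, np.where(silent, np.nan, 1.0))

    same = labels[:, None] == labels[None, :]
    iu, ju = np.triu_indices(n, 1)
    valid = ~(silent[iu] | silent[ju])
    within_vals = r[iu[valid & same[iu, ju]], ju[valid & same[iu, ju]]]
    between_vals = r[iu[valid & ~same[iu, ju]], ju[valid & ~same[iu, ju]]]
    excluded = [(int(i), int(j)) for i, j in zip(iu[~valid], ju[~valid])]
    return SCCMatrix(
        r=r,
        bin_width=bin_width,
        mean_within=float(within_vals.mean()) if within_vals.size else float("nan"),
        mean_between=float(between_vals.mean()) if between_vals.size else float("nan"),
        excluded_pairs=excluded,
    )


def experiment_scc(
    results, labels, bin_width: float = 1.0, direction: str | None = None
) -> SCCMatrix:
    """SCC over a simulated sweep: bin each step, concatenate, correlate.

    Every step's raster is binned at ``bin_width`` ms and the per-unit
    series are concatenated across steps (all steps by default, or only
    those matching ``direction``) before computing the Pearson matrix.
    """
    chosen = [r for r in results if direction is None or r.direction == direction]
    if not chosen:
        raise ValueError("no simulation results selected")
    dt = float(chosen[0].times[1] - chosen[0].times[0])
    T = float(chosen[0].times[-1]) + dt
    pieces = [binned_counts(res.raster, T, bin_width) for res in chosen]
    counts = np.concatenate(pieces, axis=1)
    return scc_matrix(counts, labels, bin_width)
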