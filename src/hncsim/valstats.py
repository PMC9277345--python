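"""Spike-train statistics for simulator equivalence checks.

Two simulator runs are compared by the distributions of three per-neuron
(or per-pair) measures over each population: the average firing rate
(FR, spks/s), the coefficient of variation of inter-spike intervals
(CV), and the Pearson correlation coefficient of spike trains binned at
2 ms (CC).  Distributions are visualised with Freedman-Diaconis
histograms and Gaussian-kernel density estimates; equivalence is
quantified with the two-sample Kolmogorov-Smirnov statistic computed on
the raw samples (never on the smoothed densities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class MeasureSamples:
    """Raw per-neuron (or per-pair) values of one measure."""

    measure: str                  # "FR" | "CV" | "CC"
    values: np.ndarray
    population: str = ""          # e.g. "EXC" / "INH"
    run: str = ""                 # provenance label
    excluded: int = 0             # units dropped by the measure's rule

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def _trains(records, neuron_ids, h_ms: float = 0.1):
    """Per-neuron sorted spike-time arrays (seconds) from engine records."""
    by_id: dict[int, list[float]] = {int(i): [] for i in neuron_ids}
    for r in records:
        if r.neuron in by_id:
            by_id[r.neuron].append(r.k * h_ms * 1e-3)
    return {i: np.asarray(ts) for i, ts in by_id.items()}


def firing_rates(records, neuron_ids, t: float, population: str = "",
                 h_ms: float = 0.1) -> MeasureSamples:
    """Per-neuron firing rate n_sp / T over ``t`` seconds (zeros included)."""
    if t <= 0:
        raise ValueError("observation interval must be positive")
    trains = _trains(records, neuron_ids, h_ms)
    values = np.array([len(trains[int(i)]) / t for i in neuron_ids])
    return MeasureSamples("FR", values, population)


def cv_isi(records, neuron_ids, population: str = "",
           h_ms: float = 0.1) -> MeasureSamples:
    """Per-neuron CV of inter-spike intervals; needs >= 3 spikes.

    Neurons with fewer spikes are excluded and counted in ``excluded``.
    """
    trains = _trains(records, neuron_ids, h_ms)
    values, excluded = [], 0
    for i in neuron_ids:
        ts = trains[int(i)]
        if len(ts) < 3:
            excluded += 1
            continue
        isi = np.diff(ts)
        values.append(isi.std() / isi.mean())
    return MeasureSamples("CV", np.array(values), population, excluded=excluded)


def pearson_cc(records, neuron_ids, t: float, bin_ms: float = 2.0,
               population: str = "", max_pairs: int | None = 20000,
               seed: int = 0, h_ms: float = 0.1) -> MeasureSamples:
    """Pairwise Pearson correlation of spike trains binned at ``bin_ms``.

    All within-population pairs are used unless their number exceeds
    ``max_pairs``, in which case pairs are sampled without replacement
    (seeded).  Zero-variance (empty or constant) trains are excluded.
    """
    n_bins = int(round(t * 1e3 / bin_ms))
    if abs(n_bins * bin_ms - t * 1e3) > 1e-6:
        raise ValueError("bin width must divide the observation interval")
    trains = _trains(records, neuron_ids, h_ms)
    ids = list(map(int, neuron_ids))
    counts = np.zeros((len(ids), n_bins))
    for row, i in enumerate(ids):
        b = (trains[i] * 1e3 / bin_ms).astype(int)
        np.add.at(counts[row], b[b < n_bins], 1)
    ok = counts.std(axis=1) > 0
    excluded = int(np.count_nonzero(~ok))
    idx = np.nonzero(ok)[0]
    pairs = [(a, b) for ii, a in enumerate(idx) for b in idx[ii + 1:]]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[s] for s in sel]
    z = counts - counts.mean(axis=1, keepdims=True)
    norm = np.sqrt((z ** 2).sum(axis=1))
    values = np.array([(z[a] @ z[b]) / (norm[a] * norm[b]) for a, b in pairs])
    return MeasureSamples("CC", values, population, excluded=excluded)


@dataclass
class Distribution:
    bin_edges: np.ndarray
    hist: np.ndarray              # probability density per bin
    grid: np.ndarray = field(default=None)
    density: np.ndarray = field(default=None)
    point_mass: float | None = None


def freedman_diaconis_width(values: np.ndarray) -> float:
    """Bin width 2 * IQR * n^(-1/3)."""
    values = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(values, [75, 25])
    return 2.0 * (q75 - q25) * len(values) ** (-1.0 / 3.0)


def distribution(samples: MeasureSamples, bw_method="scott",
                 grid_points: int = 512) -> Distribution:
    """Freedman-Diaconis histogram plus Gaussian-KDE density.

    The density integrates to one on its grid (trapezoid, within 1e-6 of
    the KDE's mass on the widened support).  An all-equal sample yields
    a point mass and no KDE.  The kernel bandwidth rule (default:
    Scott's) is configurable.
    """
    x = np.asarray(samples.values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    if np.ptp(x) == 0:
        return Distribution(bin_edges=np.array([x[0], x[0]]),
                            hist=np.array([]), point_mass=float(x[0]))
    width = freedman_diaconis_width(x)
    if width == 0:  # degenerate IQR; fall back to a single spanning bin rule
        width = np.ptp(x)
    n_bins = max(1, int(np.ceil(np.ptp(x) / width)))
    hist, edges = np.histogram(x, bins=n_bins, density=True)
    kde = sps.gaussian_kde(x, bw_method=bw_method)
    pad = 4 * x.std()
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_points)
    density = kde(grid)
    density = density / np.trapezoid(density, grid)
    return Distribution(bin_edges=edges, hist=hist, grid=grid, density=density)


def ks_compare(samples_a: MeasureSamples, samples_b: MeasureSamples):
    """Two-sample KS on the raw samples: (D, asymptotic p)."""
    a = np.asarray(samples_a.values, dtype=float)
    b = np.asarray(samples_b.values, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS comparison needs non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def compare_runs(records_a, records_b, exc_ids, inh_ids, t: float,
                 h_ms: float = 0.1, seed: int = 0) -> dict:
    """Full six-way comparison (FR/CV/CC x EXC/INH) of two spike sets.

    Returns ``{measure: {population: {"D": .., "p": .., "n_a": .., "n_b": ..}}}``.
    """
    out: dict = {}
    for measure, fn in (
        ("FR", lambda r, ids, pop: firing_rates(r, ids, t, pop, h_ms)),
        ("CV", lambda r, ids, pop: cv_isi(r, ids, pop, h_ms)),
        ("CC", lambda r, ids, pop: pearson_cc(r, ids, t, population=pop,
                                              seed=seed, h_ms=h_ms)),
    ):
        out[measure] = {}
        for pop, ids in (("EXC", exc_ids), ("INH", inh_ids)):
            sa = fn(records_a, ids, pop)
            sb = fn(records_b, ids, pop)
            if len(sa.values) == 0 or len(sb.values) == 0:
                out[measure][pop] = {"D": None, "p": None,
                                     "n_a": len(sa.values), "n_b": len(sb.values)}
                continue
            d, p = ks_compare(sa, sb)
            out[measure][pop] = {"D": d, "p": p,
                                 "n_a": len(sa.values), "n_b": len(sb.values)}
    return out
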