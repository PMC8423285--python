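"""One-step growth curve analysis: latent period, rise period, burst size.

A one-step growth experiment follows free-phage titer after a synchronized
infection.  The curve has three phases: a baseline (latent period, progeny
still intracellular), a rise (cells lysing), and a plateau (all infected
cells burst).  Burst size is the fold increase from baseline to plateau.

Extraction rules, per replicate:

* scan the curve left to right, maintaining the running geometric mean of
  the points seen so far (the baseline estimate); the first point exceeding
  baseline x ``rise_factor`` marks burst onset;
* latent period = last sampled time before that first exceedance (reported
  at sampling resolution, no interpolation);
* plateau = the maximal suffix of points whose pairwise log10 range is at
  most ``plateau_tol``, requiring at least 2 points;
* rise period = first plateau time - latent;
* burst size = geometric mean of plateau titers / baseline geometric mean.

Geometric means are used throughout because plaque titers are
log-distributed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GrowthCurve:
    """A single-replicate titer time series (minutes, PFU/mL)."""

    times: np.ndarray
    titers: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.titers = np.asarray(self.titers, dtype=float)
        if self.times.shape != self.titers.shape:
            raise ValueError("times and titers must have equal length")
        if len(self.times) < 4:
            raise ValueError("need at least 4 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.titers > 0):
            raise ValueError("titers must be positive")


@dataclass
class KineticsEstimate:
    latent_min: float
    rise_min: float
    burst_size: float
    burst_se: float
    n_replicates: int

    def to_dict(self) -> dict:
        return {
            "latent_min": self.latent_min,
            "rise_min": self.rise_min,
            "burst_size": self.burst_size,
            "burst_se": self.burst_se,
            "n_replicates": self.n_replicates,
        }


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def _analyze_one(curve: GrowthCurve, rise_factor: float, plateau_tol: float):
    """Returns (latent, rise, burst, baseline) for one replicate."""
    t, y = curve.times, curve.titers
    onset = None
    for k in range(1, len(y)):
        baseline = _geomean(y[:k])
        if y[k] > baseline * rise_factor:
            onset = k
            break
    if onset is None:
        raise ValueError(f"no burst detected in replicate {curve.replicate_id}")
    baseline = _geomean(y[:onset])
    latent = float(t[onset - 1])

    # maximal suffix with log10 range <= plateau_tol, at least 2 points,
    # starting no earlier than burst onset
    logy = np.log10(y)
    start = len(y) - 1
    for j in range(len(y) - 2, onset - 1, -1):
        if logy[j:].max() - logy[j:].min() <= plateau_tol:
            start = j
        else:
            break
    if start > len(y) - 2:
        raise ValueError(f"no plateau in replicate {curve.replicate_id}")
    plateau_titer = _geomean(y[start:])
    burst = plateau_titer / baseline
    rise = float(t[start]) - latent
    return latent, rise, burst, baseline


def estimate_kinetics(
    curves: list[GrowthCurve],
    rise_factor: float = 2.0,
    plateau_tol: float = 0.1,
) -> KineticsEstimate:
    """Estimate latent period, rise period and burst size from replicates.

    Latent and rise are medians of the per-replicate values (both live on
    the sampling grid); burst size is the mean of per-replicate bursts with
    its standard error across replicates.
    """
    if not curves:
        raise ValueError("no growth curves supplied")
    per_rep = [_analyze_one(c, rise_factor, plateau_tol) for c in curves]
    latents = np.array([p[0] for p in per_rep])
    rises = np.array([p[1] for p in per_rep])
    bursts = np.array([p[2] for p in per_rep])
    n = len(curves)
    se = float(bursts.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return KineticsEstimate(
        latent_min=float(np.median(latents)),
        rise_min=float(np.median(rises)),
        burst_size=float(bursts.mean()),
        burst_se=se,
        n_replicates=n,
    )


def moi(phage_added: float, cells: float) -> float:
    """Multiplicity of infection: PFU added per CFU present."""
    if cells <= 0:
        raise ValueError("cell count must be positive")
    if phage_added < 0:
        raise ValueError("phage count must be non-negative")
    return phage_added / cells


def read_growth_tsv(path: str | Path) -> list[GrowthCurve]:
    """Read long-format TSV (replicate, time_min, pfu_per_ml) into curves."""
    df = pd.read_csv(path, sep="\t")
    required = {"replicate", "time_min", "pfu_per_ml"}
    if not required.issubset(df.columns):
        raise ValueError(f"growth TSV must have columns {sorted(required)}")
    curves = []
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("time_min")
        curves.append(
            GrowthCurve(
                times=grp["time_min"].to_numpy(),
                titers=grp["pfu_per_ml"].to_numpy(),
                replicate_id=str(rep),
            )
        )
    return curves


def write_growth_tsv(curves: list[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, y in zip(c.times, c.titers):
            rows.append({"replicate": c.replicate_id, "time_min": t, "pfu_per_ml": y})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
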