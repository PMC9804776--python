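"""Nonparametric percentile-bootstrap intervals for variance components.

Variance components estimated by REML have awkward sampling distributions
(non-negative, often piled up at zero), so Wald intervals are unreliable.
The bootstrap here resamples the data with replacement — either individual
records or whole studies (records within a study are dependent, so the
cluster bootstrap is the conservative choice) — refits the model on each
replicate, and reports percentile intervals from the replicate estimates.

The percentile convention follows Davison & Hinkley: on R sorted replicate
values the interval endpoints are order statistics ceil((R+1)*alpha/2) and
floor((R+1)*(1-alpha/2)) (1-based), which makes tie handling deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .effects_io import EffectSizeRecord
from .mlmeta import ConvergenceError, build_model, fit_reml
from .phylo import PhyloCorrelation

__all__ = ["BootstrapResult", "bootstrap_components", "percentile_interval"]


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame  # one row per successful replicate, one col per component
    intervals: dict[str, tuple[float, float]]
    R: int
    n_failed: int
    seed: int
    unit: str

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "R": self.R,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "intervals": {k: list(v) for k, v in self.intervals.items()},
        }


def percentile_interval(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Basic percentile CI via Davison-Hinkley order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    R = len(x)
    if R == 0:
        raise ValueError("no replicate values")
    half_alpha = (1.0 - level) / 2
    # epsilon guards keep e.g. (R+1)*0.025 = 1.0000000000000002 at index 1
    lo = max(math.ceil((R + 1) * half_alpha - 1e-9), 1)
    hi = min(math.floor((R + 1) * (1 - half_alpha) + 1e-9), R)
    return float(x[lo - 1]), float(x[hi - 1])


def bootstrap_components(
    records: Sequence[EffectSizeRecord],
    R: int,
    seed: int,
    unit: str = "record",
    moderators: Sequence[str] | None = None,
    random_terms: Sequence[str] = ("study", "phylogeny", "species", "estimate"),
    A: PhyloCorrelation | None = None,
    level: float = 0.95,
    max_failure_rate: float = 0.2,
) -> BootstrapResult:
    """Percentile bootstrap CIs for every variance component.

    ``unit='record'`` resamples rows; ``unit='study'`` resamples whole
    studies with all their records (cluster bootstrap).  Each replicate
    rebuilds the model — so the phylogenetic correlation submatrix tracks
    the species actually resampled — and refits by REML.  Replicates where
    the refit fails (e.g. a resample with a rank-deficient design) are
    dropped and counted; more than ``max_failure_rate`` failures aborts.

    Reproducibility: one master seed spawns an independent substream per
    replicate, so results do not depend on execution order.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    if unit not in ("record", "study"):
        raise ValueError("unit must be 'record' or 'study'")
    records = list(records)
    studies: dict[str, list[EffectSizeRecord]] = {}
    for rec in records:
        studies.setdefault(rec.study_id, []).append(rec)
    study_ids = list(studies)

    master = np.random.SeedSequence(seed)
    children = master.spawn(R)
    rows: list[dict[str, float]] = []
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        if unit == "record":
            idx = rng.integers(0, len(records), size=len(records))
            sample = [records[i] for i in idx]
        else:
            picked = rng.integers(0, len(study_ids), size=len(study_ids))
            sample = [
                rec for j in picked for rec in studies[study_ids[j]]
            ]
        sample = _relabel(sample)
        try:
            spec = build_model(
                sample,
                moderators=moderators,
                random_terms=random_terms,
                A=A,
            )
            fit = fit_reml(spec)
        except (ValueError, ConvergenceError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        rows.append(fit.components)

    if n_failed > max_failure_rate * R:
        raise RuntimeError(
            f"{n_failed}/{R} bootstrap replicates failed to fit; model unstable"
        )
    replicates = pd.DataFrame(rows)
    intervals = {
        col: percentile_interval(replicates[col].to_numpy(), level)
        for col in replicates.columns
    }
    return BootstrapResult(
        replicates=replicates,
        intervals=intervals,
        R=R,
        n_failed=n_failed,
        seed=seed,
        unit=unit,
    )


def _relabel(sample: list[EffectSizeRecord]) -> list[EffectSizeRecord]:
    """Give duplicated resampled rows unique estimate IDs.

    A record drawn twice is two exchangeable observations in the bootstrap
    world; the estimate-level term is i.i.d. so only uniqueness matters.
    """
    from dataclasses import replace

    seen: dict[str, int] = {}
    out = []
    for rec in sample:
        count = seen.get(rec.estimate_id, 0)
        seen[rec.estimate_id] = count + 1
        if count:
            rec = replace(rec, estimate_id=f"{rec.estimate_id}#boot{count}")
        out.append(rec)
    return out
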