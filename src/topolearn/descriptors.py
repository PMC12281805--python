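"""One-dimensional summary descriptors of persistence diagrams.

For each homological dimension i the diagram is condensed into scalar
statistics of the interval lifetimes Δ = death − birth and midlives
μ = (birth + death)/2, their sum-normalized variants p = Δ/ΣΔ and
ν = μ/Σμ, the Betti number (count of finite intervals), and the
persistence entropy E = −Σ p log p (natural log).  Aggregators are
min, max, avg, std (population) and sum.

A dimension with no intervals carries NaN for all its fields — "no
topological signal" — rather than zeros, so downstream models can treat
absence explicitly.
"""

from __future__ import annotations

import math

import numpy as np

from .geometry import PersistenceDiagram

AGGREGATORS = ("min", "max", "avg", "std", "sum")
HOM_DIMS = (0, 1)

#: value of a descriptor for a homological dimension with no intervals
MISSING = float("nan")


def _agg_stats(values: np.ndarray, prefix: str) -> dict[str, float]:
    if values.size == 0:
        return {f"{prefix}_{a}": MISSING for a in AGGREGATORS}
    return {
        f"{prefix}_min": float(np.min(values)),
        f"{prefix}_max": float(np.max(values)),
        f"{prefix}_avg": float(np.mean(values)),
        f"{prefix}_std": float(np.std(values)),  # population std
        f"{prefix}_sum": float(np.sum(values)),
    }


def descriptor_names(hom_dims: tuple[int, ...] = HOM_DIMS) -> list[str]:
    """Stable, documented column order of the descriptor vector."""
    names = ["n_points"]
    for i in hom_dims:
        names += [f"betti_{i}", f"betti_{i}_norm"]
        for family in ("lifetime", "lifetime_norm", "midlife", "midlife_norm"):
            names += [f"{family}_{i}_{a}" for a in AGGREGATORS]
        names += [f"entropy_{i}"]
    return names


def compute_descriptors(diag: PersistenceDiagram) -> dict[str, float]:
    """Compute the descriptor vector of a finalized diagram.

    Returns a dict keyed by the names of :func:`descriptor_names`.
    Normalized statistics are scale-invariant: multiplying every birth
    and death by c > 0 leaves them (and the entropy) unchanged.
    """
    out: dict[str, float] = {"n_points": float(diag.n_points)}
    for i in HOM_DIMS:
        lifetimes = diag.lifetimes(i)
        midlives = diag.midlives(i)
        betti = lifetimes.size
        out[f"betti_{i}"] = float(betti) if betti else MISSING
        out[f"betti_{i}_norm"] = (
            float(betti) / diag.n_points if betti and diag.n_points else MISSING
        )
        out.update(_agg_stats(lifetimes, f"lifetime_{i}"))
        out.update(_agg_stats(midlives, f"midlife_{i}"))
        if betti:
            p = lifetimes / lifetimes.sum()  # lifetimes > 0 by construction
            nu = midlives / midlives.sum()
            out.update(_agg_stats(p, f"lifetime_norm_{i}"))
            out.update(_agg_stats(nu, f"midlife_norm_{i}"))
            out[f"entropy_{i}"] = float(-np.sum(p * np.log(p)))
        else:
            out.update(_agg_stats(np.empty(0), f"lifetime_norm_{i}"))
            out.update(_agg_stats(np.empty(0), f"midlife_norm_{i}"))
            out[f"entropy_{i}"] = MISSING
    return out


def is_missing(value: float) -> bool:
    return isinstance(value, float) and math.isnan(value)
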