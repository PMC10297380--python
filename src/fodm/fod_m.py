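"""Environment-modified reference field (FOD-M) and the K parameter fit.

For a non-aqueous folding environment the Gaussian reference T is mixed with
its normalized inverse (Tmax - T, hydrophobicity exposed at the surface,
polar centre):

    M(K) = normalize( T + K * normalize(Tmax - T) )

K = 0 is the pure-water micelle reference; growing K means growing
participation of a membrane-like environment.  The best K for a structure is
the one minimizing D_KL(O | M(K)), found by a grid scan so the whole
divergence-vs-K curve is available as an output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from fodm.fod_core import HydroProfile, kl_divergence


@dataclass
class MField:
    """The mixed reference distribution for one K."""

    k: float
    values: HydroProfile                 # role "M"
    t_max: float
    t_component: np.ndarray              # normalized T
    inverse_component: np.ndarray        # normalized (Tmax - T)


@dataclass
class KFit:
    """Result of the grid scan over K."""

    k_best: float
    dkl_OM_best: float
    scan: list[tuple[float, float]]
    grid_step: float


def inverse_profile(t: HydroProfile) -> HydroProfile:
    """Normalized inverse field: raw_i = max(T) - T_i, then sum-1 normalization.

    The residue at the T maximum maps to 0.  A uniform T has an identically
    zero inverse and is rejected.
    """
    raw = t.values.max() - t.values
    total = raw.sum()
    if total <= 0:
        raise ValueError("T is uniform: inverse field is identically zero")
    return HydroProfile("M_inv", raw / total, t.residue_keys)


def m_profile(t: HydroProfile, k: float) -> MField:
    """Build M(K) = normalize(T + K * normalize(Tmax - T))."""
    if k < 0:
        raise ValueError("K must be >= 0")
    if k == 0:
        mixed = t.values.copy()
        inv = np.zeros_like(t.values)
    else:
        inv = inverse_profile(t).values
        mixed = t.values + k * inv
    mixed = mixed / mixed.sum()
    return MField(
        k=float(k),
        values=HydroProfile("M", mixed, t.residue_keys),
        t_max=float(t.values.max()),
        t_component=t.values.copy(),
        inverse_component=inv,
    )


def fit_k(o: HydroProfile, t: HydroProfile, k_max: float = 3.0,
          step: float = 0.1, refine: bool = False) -> KFit:
    """Scan K over {0, step, ..., k_max}, minimizing D_KL(O|M(K)).

    Ties go to the smallest K (the most water-like environment).  With
    ``refine`` a second pass at step/10 around the coarse optimum sharpens
    k_best; the returned scan then contains both passes, sorted by K.
    """
    if len(o) != len(t):
        raise ValueError("O and T must have the same length")
    if k_max < 0 or step <= 0:
        raise ValueError("need k_max >= 0 and step > 0")
    if np.ptp(t.values) == 0:
        raise ValueError("T is uniform: M field degenerate for K > 0")

    n_steps = int(round(k_max / step))
    grid = [round(i * step, 10) for i in range(n_steps + 1)]
    scan = [(k, kl_divergence(o, m_profile(t, k).values)) for k in grid]
    k_best, d_best = min(scan, key=lambda kv: (kv[1], kv[0]))

    if refine:
        fine_step = step / 10
        lo = max(0.0, k_best - step)
        hi = min(k_max, k_best + step)
        n_fine = int(round((hi - lo) / fine_step))
        fine = [round(lo + i * fine_step, 10) for i in range(n_fine + 1)]
        extra = [(k, kl_divergence(o, m_profile(t, k).values))
                 for k in fine if k not in dict(scan)]
        scan = sorted(scan + extra)
        k_best, d_best = min(scan, key=lambda kv: (kv[1], kv[0]))
        step = fine_step

    return KFit(k_best=float(k_best), dkl_OM_best=float(d_best),
                scan=scan, grid_step=step)


def write_kscan_tsv(path, fit: KFit) -> None:
    """Two-column (k, dkl_OM) TSV of the scan curve."""
    with open(path, "w") as f:
        f.write("k\tdkl_OM_bits\n")
        for k, d in fit.scan:
            f.write(f"{k:.10g}\t{d:.10g}\n")
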