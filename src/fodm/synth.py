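"""Synthetic micelle-like residue clouds with controllable discordance.

The generator emulates the spatial picture the FOD model idealizes: points in
an ellipsoid whose intrinsic hydrophobicity falls off linearly from 1 at the
centre to 0 at the surface (an ideal micelle).  The ``discordance`` dial in
[0, 1] swaps the hydrophobicities of matched centre/surface residue pairs —
at 1 the radial ordering is fully inverted (hydrophobicity exposed, polar
core) while the *marginal* hydrophobicity distribution is untouched, so only
the spatial ordering that RD measures changes.

Hydrophobicities are quantized onto a real amino-acid scale so that the
generated clouds carry valid residue names and round-trip through the PDB
writer and the main CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fodm.fod_core import HydroProfile
from fodm.fod_m import m_profile
from fodm.structure_io import HydroScale, ResidueCloud, ResidueRecord, bundled_scale


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic cloud."""

    n_residues: int = 100
    radius: float = 15.0                       # Å, typical small-domain scale
    discordance: float = 0.0                   # 0 ideal micelle .. 1 inverted
    aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("need at least 10 residues")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.discordance <= 1.0):
            raise ValueError("discordance must lie in [0, 1]")
        if len(self.aspect) != 3 or any(a <= 0 for a in self.aspect):
            raise ValueError("aspect must be 3 positive factors")


def generate_cloud(spec: SynthSpec, scale: HydroScale | None = None) -> ResidueCloud:
    """Sample a deterministic micelle-like cloud according to ``spec``.

    Points are uniform in the ellipsoid radius*aspect; the hydrophobicity ramp
    1 - r (r = scaled radial coordinate in [0, 1]) is quantized to the nearest
    entry of ``scale`` (default: the bundled scale), after which a fraction
    ``discordance`` of innermost/outermost pairs swap values and names.
    """
    scale = scale if scale is not None else bundled_scale()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues

    direction = rng.standard_normal((n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r_unit = rng.random(n) ** (1.0 / 3.0)       # uniform-in-ball radii
    pos = direction * r_unit[:, None] * spec.radius * np.asarray(spec.aspect)

    # quantize the linear ramp onto the scale's 20 values
    names_sorted = sorted(scale.values)
    scale_vals = np.array([scale.values[a] for a in names_sorted])
    ramp = 1.0 - r_unit
    nearest = np.argmin(np.abs(scale_vals[None, :] - ramp[:, None]), axis=1)
    names = [names_sorted[i] for i in nearest]
    hydro = scale_vals[nearest].copy()

    order = np.argsort(r_unit)                  # innermost first
    n_pairs = int(round(spec.discordance * n / 2))
    for i in range(n_pairs):
        a, b = order[i], order[-(i + 1)]
        hydro[a], hydro[b] = hydro[b], hydro[a]
        names[a], names[b] = names[b], names[a]

    records = [
        ResidueRecord(
            chain_id="A",
            seq_number=i + 1,
            insertion_code="",
            residue_name=names[i],
            effective_position=pos[i],
            intrinsic_hydrophobicity=float(hydro[i]),
        )
        for i in range(n)
    ]
    return ResidueCloud(
        records,
        source_id=f"synth(seed={spec.seed})",
        selection=f"synthetic micelle, discordance={spec.discordance}",
    )


def generate_profile_pair(n: int, k_true: float, noise: float,
                          seed: int) -> tuple[HydroProfile, HydroProfile]:
    """A (T, O) pair with O built from T through the mixed field at ``k_true``.

    T is a random positive normalized profile; O = M(k_true) perturbed on the
    simplex by multiplicative log-normal noise of scale ``noise`` and
    renormalized.  noise = 0 makes K recovery exact on the fit grid.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if k_true < 0 or noise < 0:
        raise ValueError("k_true and noise must be >= 0")
    rng = np.random.default_rng(seed)
    raw_t = rng.uniform(0.2, 1.0, n)
    t = HydroProfile("T", raw_t / raw_t.sum())
    o_vals = m_profile(t, k_true).values.values
    if noise > 0:
        o_vals = o_vals * np.exp(noise * rng.standard_normal(n))
        o_vals = o_vals / o_vals.sum()
    return t, HydroProfile("O", o_vals)
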