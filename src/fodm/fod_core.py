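"""Core fuzzy-oil-drop scoring: T, O, R profiles, divergence entropy, RD.

The theoretical profile T spreads a 3D Gaussian over the molecular body
(hydrophobicity peaking at the centre — the idealized micelle); the observed
profile O sums pairwise Levitt contact contributions of intrinsic
hydrophobicities within a distance cutoff; R is the uniform 1/N reference.
All three are normalized to sum 1 so they compare as discrete distributions
via the base-2 Kullback–Leibler divergence ("divergence entropy").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from fodm.structure_io import ResidueCloud, ResidueKey

DEFAULT_CUTOFF = 9.0  # Å, the conventional Levitt contact cutoff

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class GaussianField:
    """3D Gaussian hydrophobicity field: centre, principal frame, per-axis sigmas."""

    center: np.ndarray          # (3,)
    axes: np.ndarray            # (3,3), rows are unit principal axes
    sigmas: np.ndarray          # (3,), Å

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigmas) <= 0):
            raise ValueError(f"sigmas must be positive, got {self.sigmas}")
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express points in the principal frame (centered, rotated)."""
        return (np.atleast_2d(points) - self.center) @ self.axes.T


@dataclass
class HydroProfile:
    """A per-residue distribution (role T, O, R or M): nonnegative, sums to 1."""

    role: str
    values: np.ndarray
    residue_keys: Optional[list[ResidueKey]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("profile needs at least 2 entries")
        if np.any(self.values < 0):
            raise ValueError(f"{self.role} profile has negative entries")
        total = self.values.sum()
        if not np.isclose(total, 1.0, atol=_NORM_TOL, rtol=0):
            raise ValueError(f"{self.role} profile sums to {total}, not 1")
        if self.residue_keys is not None and len(self.residue_keys) != len(self.values):
            raise ValueError("residue_keys length mismatch")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FODResult:
    """Summary of one FOD scoring run."""

    dkl_OT: float
    dkl_OR: float
    rd: float
    classification: str                 # "core_present" | "core_absent"
    n_residues: int
    excluded: list[ResidueKey] = field(default_factory=list)
    scale_name: str = ""
    cutoff: float = DEFAULT_CUTOFF
    k: Optional[float] = None           # filled by the FOD-M layer
    dkl_OM: Optional[float] = None
    field_params: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {
            "dkl_OT_bits": self.dkl_OT,
            "dkl_OR_bits": self.dkl_OR,
            "rd": self.rd,
            "classification": self.classification,
            "n_residues": self.n_residues,
            "excluded": [list(k) for k in self.excluded],
            "scale_name": self.scale_name,
            "cutoff_angstrom": self.cutoff,
        }
        if self.k is not None:
            d["k"] = self.k
            d["dkl_OM_bits"] = self.dkl_OM
        if self.field_params is not None:
            d["field"] = self.field_params
        return d


# ---------------------------------------------------------------------------
# field fitting

def fit_gaussian_field(cloud: ResidueCloud | np.ndarray) -> GaussianField:
    """Fit the 3D Gaussian field to an effective-atom cloud.

    Centre = centroid of the points; axes = principal axes of the centered
    cloud ordered by descending spread (sign fixed so each axis' largest
    loading is positive, third axis flipped if needed for a right-handed
    frame); sigma per axis = (max |centered coordinate along axis|) / 3,
    so the molecule spans ±3 sigma.
    """
    pts = cloud if isinstance(cloud, np.ndarray) else cloud.positions
    pts = np.asarray(pts, dtype=float)
    center = pts.mean(axis=0)
    centered = pts - center
    cov = centered.T @ centered / len(pts)
    eigval, eigvec = np.linalg.eigh(cov)          # ascending
    order = np.argsort(eigval)[::-1]
    axes = eigvec[:, order].T                      # rows = axes, descending spread
    for i in range(3):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    local = centered @ axes.T
    extents = np.abs(local).max(axis=0)
    if np.all(extents <= 0):
        raise ValueError("all points coincident: zero extent on every axis")
    if np.any(extents <= 0):
        smallest_positive = extents[extents > 0].min()
        warnings.warn(
            "zero extent on a principal axis; sigma taken from the smallest "
            "positive extent", RuntimeWarning, stacklevel=2)
        extents = np.where(extents > 0, extents, smallest_positive)
    return GaussianField(center=center, axes=axes, sigmas=extents / 3.0)


# ---------------------------------------------------------------------------
# profiles

def theoretical_profile(cloud: ResidueCloud | np.ndarray,
                        gfield: GaussianField) -> HydroProfile:
    """T: the Gaussian field evaluated at each effective atom, normalized."""
    pts = cloud if isinstance(cloud, np.ndarray) else cloud.positions
    local = gfield.to_local(np.asarray(pts, dtype=float))
    log_t = -0.5 * np.sum((local / gfield.sigmas) ** 2, axis=1)
    raw = np.exp(log_t - log_t.max())   # stable: largest term is 1
    keys = None if isinstance(cloud, np.ndarray) else cloud.keys
    return HydroProfile("T", raw / raw.sum(), keys)


def levitt_weight(x: np.ndarray | float) -> np.ndarray | float:
    """Levitt contact weight g(x) for x = r/c in [0,1]: 1 at contact, 0 at cutoff."""
    x2 = np.square(x)
    return 1.0 - 0.5 * (7 * x2 - 9 * x2**2 + 5 * x2**3 - x2**4)


def observed_profile(cloud: ResidueCloud, cutoff: float = DEFAULT_CUTOFF,
                     include_self: bool = False) -> HydroProfile:
    """O: summed pairwise Levitt interactions of intrinsic hydrophobicities.

    O_i (raw) = sum over j != i with r_ij <= cutoff of (H_i + H_j) * g(r_ij/c);
    pairs beyond the cutoff contribute nothing.  ``include_self`` adds the
    degenerate j = i term (2 H_i, since g(0) = 1) for sensitivity checks.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    h = cloud.hydrophobicities
    if np.any(~np.isfinite(h)):
        raise ValueError("intrinsic hydrophobicities not assigned; "
                         "call assign_hydrophobicity first")
    pts = cloud.positions
    diff = pts[:, None, :] - pts[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    g = levitt_weight(r / cutoff)
    mask = r <= cutoff
    if not include_self:
        np.fill_diagonal(mask, False)
    pair_h = h[:, None] + h[None, :]
    raw = np.where(mask, pair_h * g, 0.0).sum(axis=1)
    total = raw.sum()
    if total <= 0:
        cause = ("all residue pairs are farther apart than the cutoff"
                 if not mask.any() else "all intrinsic hydrophobicities are zero")
        raise ValueError(f"observed profile sums to zero: {cause}")
    return HydroProfile("O", raw / total, cloud.keys)


def uniform_profile(n: int, residue_keys: Optional[list[ResidueKey]] = None) -> HydroProfile:
    """R: the no-differentiation reference, 1/N per residue."""
    if n < 2:
        raise ValueError("uniform profile needs n >= 2")
    return HydroProfile("R", np.full(n, 1.0 / n), residue_keys)


# ---------------------------------------------------------------------------
# divergence and classification

def kl_divergence(p: HydroProfile | np.ndarray, q: HydroProfile | np.ndarray) -> float:
    """Base-2 Kullback–Leibler divergence sum p_i log2(p_i/q_i), in bits.

    Terms with p_i = 0 contribute 0; q_i = 0 where p_i > 0 is an error.
    """
    pv = p.values if isinstance(p, HydroProfile) else np.asarray(p, dtype=float)
    qv = q.values if isinstance(q, HydroProfile) else np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError(f"length mismatch: {pv.shape} vs {qv.shape}")
    support = pv > 0
    if np.any(qv[support] <= 0):
        raise ValueError("q is zero on the support of p: divergence undefined")
    return float(np.sum(pv[support] * np.log2(pv[support] / qv[support])))


def relative_distance(dkl_OT: float, dkl_OR: float) -> float:
    """RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)); < 0.5 means a centric core."""
    if dkl_OT < 0 or dkl_OR < 0:
        raise ValueError("divergences must be nonnegative")
    denom = dkl_OT + dkl_OR
    if denom == 0:
        raise ValueError("RD undefined: O identical to both T and R")
    return dkl_OT / denom


def score_structure(cloud: ResidueCloud,
                    exclude: Optional[Iterable[ResidueKey]] = None,
                    cutoff: float = DEFAULT_CUTOFF,
                    scale_name: str = "",
                    include_self: bool = False) -> FODResult:
    """Full FOD scoring of a hydrophobicity-assigned cloud.

    Excluded residues (author numbering keys) are removed *before* field
    fitting, so both the Gaussian parameters and all profiles are re-derived
    over the retained residues.
    """
    excluded = list(exclude) if exclude else []
    work = cloud.without(excluded) if excluded else cloud
    gfield = fit_gaussian_field(work)
    t = theoretical_profile(work, gfield)
    o = observed_profile(work, cutoff=cutoff, include_self=include_self)
    r = uniform_profile(len(work), work.keys)
    dkl_ot = kl_divergence(o, t)
    dkl_or = kl_divergence(o, r)
    rd = relative_distance(dkl_ot, dkl_or)
    return FODResult(
        dkl_OT=dkl_ot,
        dkl_OR=dkl_or,
        rd=rd,
        classification="core_present" if rd < 0.5 else "core_absent",
        n_residues=len(work),
        excluded=[k if len(k) == 3 else (*k, "") for k in excluded],
        scale_name=scale_name,
        cutoff=cutoff,
        field_params={
            "center": gfield.center.tolist(),
            "axes": gfield.axes.tolist(),
            "sigmas": gfield.sigmas.tolist(),
            "sigma_rule": "extent/3 per principal axis",
        },
    )


def write_profiles_tsv(path, cloud: ResidueCloud, profiles: Sequence[HydroProfile]) -> None:
    """Write per-residue profiles side by side as TSV (index, residue, one column per role)."""
    roles = [p.role for p in profiles]
    with open(path, "w") as f:
        f.write("index\tchain\tresnum\ticode\tresname\t" + "\t".join(roles) + "\n")
        for i, rec in enumerate(cloud.records):
            vals = "\t".join(f"{p.values[i]:.10g}" for p in profiles)
            f.write(f"{i+1}\t{rec.chain_id}\t{rec.seq_number}\t"
                    f"{rec.insertion_code or '.'}\t{rec.residue_name}\t{vals}\n")


def read_profiles_tsv(path) -> dict[str, HydroProfile]:
    """Read back a profiles TSV written by :func:`write_profiles_tsv`."""
    with open(path) as f:
        header = f.readline().rstrip("\n").split("\t")
        roles = header[5:]
        cols: dict[str, list[float]] = {r: [] for r in roles}
        keys: list[ResidueKey] = []
        for line in f:
            parts = line.rstrip("\n").split("\t")
            icode = "" if parts[3] == "." else parts[3]
            keys.append((parts[1], int(parts[2]), icode))
            for r, v in zip(roles, parts[5:]):
                cols[r].append(float(v))
    return {r: HydroProfile(r, np.array(v), list(keys)) for r, v in cols.items()}
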