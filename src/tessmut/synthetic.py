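"""Download-free synthetic fixtures: protein-like traces and activities.

The generators produce geometric stand-ins for folded proteins — compact
self-avoiding C-alpha walks with the ~3.8 Å virtual bond of real protein
backbones — together with toy training potentials and activity labels
statistically coupled to computed residual scores.  They exercise
tessellation topology, scoring algebra and the machine-learning plumbing
end to end; they are not physically realistic decoys.

All randomness flows from the seed in the spec; no generator consults
global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import ActivityRecord, classify_activity
from .mutagenesis import VariantSpec, residual_profile
from .potential import FourBodyPotential, derive_potential
from .structure_io import AMINO_ACIDS, CoarseStructure, ResidueSite, write_calpha_pdb
from .tessellation import Tessellation, tessellate


class SyntheticError(RuntimeError):
    """Raised when a fixture cannot be generated under its constraints."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic trace; identical specs give identical output.

    ``step`` is the consecutive C-alpha spacing in Å (3.8 as in real
    backbones); ``compactness`` scales the inward bias that keeps the walk
    inside a globule of radius ~3·n^(1/3) Å (roughly protein-like packing
    density); ``min_separation`` is the self-avoidance distance between
    non-consecutive residues.
    """

    n_residues: int = 100
    chains: int = 1
    step: float = 3.8
    compactness: float = 1.0
    min_separation: float = 4.0
    interface_gap: float = 6.0
    asymmetry: float = 0.0
    composition: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise SyntheticError("n_residues must be >= 10")
        if self.chains not in (1, 2):
            raise SyntheticError("chains must be 1 (monomer) or 2 (homodimer)")


def _walk(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding random walk with fixed step length."""
    radius = 3.0 * spec.n_residues ** (1.0 / 3.0)
    max_restarts = 50
    for _ in range(max_restarts):
        coords = [np.zeros(3)]
        failed = False
        for _i in range(1, spec.n_residues):
            pos = coords[-1]
            placed = False
            for _try in range(60):
                direction = rng.normal(size=3)
                r = np.linalg.norm(pos)
                if r > 1e-9:
                    # bias inward, stronger the further outside the target globule
                    pull = spec.compactness * max(r / radius - 0.5, 0.0)
                    direction = direction - pull * (pos / r) * np.linalg.norm(direction)
                direction /= np.linalg.norm(direction)
                candidate = pos + spec.step * direction
                prev = np.asarray(coords[:-1])
                if len(prev) and np.min(np.linalg.norm(prev - candidate, axis=1)) < spec.min_separation:
                    continue
                coords.append(candidate)
                placed = True
                break
            if not placed:
                failed = True
                break
        if not failed:
            return np.asarray(coords)
    raise SyntheticError(
        "self-avoiding walk failed after bounded retries; lower compactness"
    )


def synthetic_structure(spec: SyntheticSpec) -> CoarseStructure:
    """Generate a reproducible protein-like trace (monomer or homodimer).

    Homodimer mode mirrors the chain through a plane beyond its maximal
    x-coordinate, ``interface_gap`` Å away, with an identical sequence —
    the two chains share author numbering, as chain copies of a
    homodimer do.
    """
    rng = np.random.default_rng(spec.seed)
    coords_a = _walk(spec, rng)
    probs = None
    if spec.composition is not None:
        probs = np.asarray(spec.composition, dtype=float)
        probs = probs / probs.sum()
    sequence = rng.choice(list(AMINO_ACIDS), size=spec.n_residues, p=probs)
    chains = [("A", coords_a)]
    if spec.chains == 2:
        mirror_x = coords_a[:, 0].max() + spec.interface_gap / 2.0
        coords_b = coords_a.copy()
        coords_b[:, 0] = 2.0 * mirror_x - coords_b[:, 0]
        if spec.asymmetry > 0:
            # crystal-like chain asymmetry: subtle coordinate shifts break
            # the exact mirror symmetry, as in real homodimer structures
            coords_b += rng.normal(scale=spec.asymmetry, size=coords_b.shape)
        chains.append(("B", coords_b))
    sites: list[ResidueSite] = []
    for chain_id, coords in chains:
        for i in range(spec.n_residues):
            x, y, z = (float(v) for v in coords[i])
            sites.append(ResidueSite(chain_id, i + 1, len(sites),
                                     str(sequence[i]), (x, y, z)))
    return CoarseStructure(sites, source_id=f"synthetic-{spec.seed}",
                           chain_order=[c for c, _ in chains])


def synthetic_pdb_text(spec: SyntheticSpec) -> str:
    """The same trace rendered as CA-only PDB text."""
    return write_calpha_pdb(synthetic_structure(spec))


def synthetic_training_potential(n_structures: int = 25, n_residues: int = 100,
                                 seed: int = 0, pseudocount: float = 1.0,
                                 edge_cutoff: float = 12.0) -> FourBodyPotential:
    """Toy four-body potential derived from a set of synthetic globules.

    A handful of ~100-residue traces covers only a fraction of the 8855
    quadruplet types, so the default pseudocount of 1 keeps every
    quadruplet scoreable during mutagenesis.
    """
    tessellations = [
        tessellate(synthetic_structure(
            SyntheticSpec(n_residues=n_residues, seed=seed * 10_000 + k)),
            edge_cutoff=edge_cutoff)
        for k in range(n_structures)
    ]
    return derive_potential(tessellations, pseudocount=pseudocount)


def random_variants(structure: CoarseStructure, n_variants: int,
                    seed: int = 0) -> list[VariantSpec]:
    """Distinct random single-residue substitutions over chain A positions."""
    rng = np.random.default_rng(seed)
    chain_a = structure.chain(structure.chain_order[0])
    pool = [
        VariantSpec(site.res_type, site.author_resnum, repl)
        for site in chain_a
        for repl in AMINO_ACIDS if repl != site.res_type
    ]
    if n_variants > len(pool):
        raise SyntheticError(f"cannot draw {n_variants} distinct variants from {len(pool)}")
    idx = rng.choice(len(pool), size=n_variants, replace=False)
    return [pool[i] for i in sorted(idx)]


def calibrate_offset(residuals: np.ndarray, slope: float = 1.0,
                     threshold: float = -2.0,
                     target_affected: float = 631.0 / 1084.0) -> float:
    """Baseline shift putting ~``target_affected`` of noiseless labels below threshold.

    The experimental Gal4 set is 453 unaffected / 631 affected (42%/58%),
    and synthetic labels are calibrated to that class balance.  A toy
    potential derived from random-sequence training globules yields a
    roughly symmetric residual distribution, so the balance is set by an
    additive offset — the analog of the wild-type activity baseline —
    rather than by slope alone: offset = threshold − slope·quantile.
    """
    q = float(np.quantile(np.asarray(residuals, dtype=float), target_affected))
    return threshold - slope * q


def synthetic_activity(variants: list[VariantSpec], residuals: np.ndarray,
                       slope: float = 1.0, noise_sd: float = 0.5,
                       threshold: float = -2.0, offset: float = 0.0,
                       seed: int = 0) -> list[ActivityRecord]:
    """Activity labels coupled to residual scores.

    log2(effect size) = slope · residual + offset + Gaussian(0, noise_sd);
    the three-way and binary categories follow from the 0.0 / threshold
    cutpoints.
    """
    if noise_sd < 0:
        raise SyntheticError("noise_sd must be >= 0")
    residuals = np.asarray(residuals, dtype=float)
    if len(variants) != len(residuals):
        raise SyntheticError("one residual score per variant required")
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=noise_sd, size=len(residuals)) if noise_sd > 0 else np.zeros(len(residuals))
    log2 = slope * residuals + offset + noise
    return [
        ActivityRecord(variant=v, log2_effect=float(val),
                       **classify_activity(float(val), threshold=threshold))
        for v, val in zip(variants, log2)
    ]


@dataclass
class SyntheticStudy:
    """A complete synthetic variant study: everything the pipeline needs."""

    structure: CoarseStructure
    tessellation: Tessellation
    potential: FourBodyPotential
    variants: list[VariantSpec]
    activities: list[ActivityRecord]
    residuals: np.ndarray
    slope: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.5


def synthetic_variant_study(seed: int = 0, n_residues: int = 100, chains: int = 1,
                            n_variants: int = 400, noise_sd: float = 0.5,
                            n_training: int = 25, slope: float = 1.0,
                            offset: float | None = None) -> SyntheticStudy:
    """Generate structure, potential, variants and coupled activities.

    With ``offset=None`` the activity baseline is calibrated so the
    noiseless class balance matches the experimental 453/631
    unaffected/affected split.
    """
    spec = SyntheticSpec(n_residues=n_residues, chains=chains, seed=seed)
    structure = synthetic_structure(spec)
    tess = tessellate(structure)
    potential = synthetic_training_potential(n_structures=n_training,
                                             seed=seed + 1)
    variants = random_variants(structure, n_variants, seed=seed + 2)
    residuals = np.array([
        residual_profile(tess, potential, v).residual_score for v in variants
    ])
    if offset is None:
        offset = calibrate_offset(residuals, slope=slope)
    activities = synthetic_activity(variants, residuals, slope=slope,
                                    offset=offset, noise_sd=noise_sd,
                                    seed=seed + 3)
    return SyntheticStudy(structure=structure, tessellation=tess,
                          potential=potential, variants=variants,
                          activities=activities, residuals=residuals,
                          slope=slope, offset=offset, noise_sd=noise_sd)
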