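"""Structure scoring and computational mutagenesis.

Given a tessellation and a four-body potential, this module computes:

* the *total potential* of a structure (sum of tetrahedron scores);
* the *residue environment score* (RES) of each position — the sum of
  scores of all tetrahedra sharing its C-alpha vertex — whose vector is
  the 3D-1D potential profile;
* the *residual profile* of a variant: the mutant-minus-native
  difference of RES vectors, whose components are environmental
  perturbation (EP) scores, and the scalar *residual score* (mutant
  total minus native total);
* the *comprehensive mutational profile* (CMP): per position, the mean
  residual score of all 19 substitutions.

A substitution never moves coordinates: only the residue label at the
fixed C-alpha changes, so only tetrahedra incident to mutated vertices
need rescoring.  In a homodimer a variant relabels the same author
position in both chains simultaneously.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .potential import FourBodyPotential, PotentialError, quadruplet_key
from .structure_io import AMINO_ACIDS
from .tessellation import Tessellation

#: Physicochemical clusters used to call a substitution conservative.
#: Cysteine is a singleton, so every substitution involving C is
#: non-conservative.
PHYSICOCHEMICAL_CLUSTERS = (
    frozenset("ASTGP"),
    frozenset("DENQ"),
    frozenset("RKH"),
    frozenset("FYW"),
    frozenset("VLIM"),
    frozenset("C"),
)


class MutagenesisError(ValueError):
    """Raised for invalid variants or unscoreable structures."""


@dataclass(frozen=True)
class VariantSpec:
    """A single-residue substitution, addressed by author residue number.

    In a multimeric structure the substitution applies simultaneously at
    every chain copy of ``position``.
    """

    native: str
    position: int
    replacement: str

    def __post_init__(self) -> None:
        for letter in (self.native, self.replacement):
            if letter not in AMINO_ACIDS:
                raise MutagenesisError(f"unknown residue letter {letter!r}")
        if self.native == self.replacement:
            raise MutagenesisError(
                f"native and replacement are both {self.native!r}: not a variant"
            )

    def __str__(self) -> str:
        return f"{self.native}{self.position}{self.replacement}"


_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_variant(text: str) -> VariantSpec:
    """Parse ``C14E``-style variant strings."""
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise MutagenesisError(f"bad variant syntax {text!r} (expected e.g. C14E)")
    return VariantSpec(m.group(1), int(m.group(2)), m.group(3))


@dataclass
class PotentialProfile:
    """Per-position RES vector and the structure's total potential."""

    res: np.ndarray
    total_potential: float


@dataclass
class ResidualProfile:
    """EP vector (mutant RES − native RES) and scalar residual score."""

    ep: np.ndarray
    residual_score: float
    mutated_sites: tuple[int, ...] = ()

    @property
    def nonzero_positions(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.ep)]


@dataclass
class CmpProfile:
    """Per-position mean residual score over the 19 substitutions."""

    cmp: np.ndarray
    c_cmp: np.ndarray = field(default=None)  # conservative submean
    nc_cmp: np.ndarray = field(default=None)  # non-conservative submean


def _tet_scores(tess: Tessellation, potential: FourBodyPotential) -> list[float]:
    seq = tess.structure.sequence
    scores = []
    for tet in tess.tetrahedra:
        key = quadruplet_key(seq[v] for v in tet.vertex_ids)
        try:
            scores.append(potential.score(key))
        except PotentialError as exc:
            raise MutagenesisError(
                f"tetrahedron {tet.vertex_ids} unscoreable: {exc}"
            ) from exc
    return scores


def total_potential(tess: Tessellation, potential: FourBodyPotential) -> float:
    """Sum of quadruplet scores over all retained tetrahedra."""
    if not tess.tetrahedra:
        raise MutagenesisError("tessellation has zero retained tetrahedra")
    return float(sum(_tet_scores(tess, potential)))


def residue_environment_profile(tess: Tessellation,
                                potential: FourBodyPotential) -> PotentialProfile:
    """RES per position; Σ RES = 4 × total potential by construction."""
    if not tess.tetrahedra:
        raise MutagenesisError("tessellation has zero retained tetrahedra")
    scores = _tet_scores(tess, potential)
    res = np.zeros(len(tess.structure))
    for tet, s in zip(tess.tetrahedra, scores):
        for v in tet.vertex_ids:
            res[v] += s
    return PotentialProfile(res=res, total_potential=float(sum(scores)))


def _resolve_targets(tess: Tessellation, variant: VariantSpec,
                     chain: str | None = None) -> list[int]:
    sites = tess.structure.sites_at_label(variant.position)
    if chain is not None:
        sites = [s for s in sites if s.chain_id == chain]
    if not sites:
        where = f"chain {chain}" if chain else "structure"
        raise MutagenesisError(f"position {variant.position} not found in {where}")
    for s in sites:
        if s.res_type != variant.native:
            raise MutagenesisError(
                f"native mismatch for {variant}: structure has "
                f"{s.res_type} at {s.chain_id}:{s.author_resnum}"
            )
    return [s.flat_index for s in sites]


def residual_profile(tess: Tessellation, potential: FourBodyPotential,
                     variant: VariantSpec, chain: str | None = None) -> ResidualProfile:
    """EP vector and residual score of a variant by incremental rescoring.

    Only tetrahedra incident to the mutated vertices are rescored.  With
    ``chain`` given, the substitution is applied at that chain's copy
    only (the chain-split experiments); by default it applies at every
    chain copy of the author position.
    """
    targets = _resolve_targets(tess, variant, chain)
    target_set = set(targets)
    seq = list(tess.structure.sequence)
    ep = np.zeros(len(tess.structure))
    residual = 0.0
    seen: set[int] = set()
    for t in targets:
        seen.update(tess.incident.get(t, ()))
    for ti in sorted(seen):
        tet = tess.tetrahedra[ti]
        old_key = quadruplet_key(seq[v] for v in tet.vertex_ids)
        new_key = quadruplet_key(
            variant.replacement if v in target_set else seq[v]
            for v in tet.vertex_ids
        )
        try:
            delta = potential.score(new_key) - potential.score(old_key)
        except PotentialError as exc:
            raise MutagenesisError(f"variant {variant}: {exc}") from exc
        residual += delta
        for v in tet.vertex_ids:
            ep[v] += delta
    return ResidualProfile(ep=ep, residual_score=float(residual),
                           mutated_sites=tuple(targets))


def substitution_class(native: str, replacement: str) -> str:
    """``'C'`` (conservative, same physicochemical cluster) or ``'NC'``."""
    if native == replacement:
        raise MutagenesisError("identical residues do not define a substitution")
    for cluster in PHYSICOCHEMICAL_CLUSTERS:
        if native in cluster and replacement in cluster:
            return "C"
    if not {native, replacement} <= set(AMINO_ACIDS):
        raise MutagenesisError(f"unknown residue in pair ({native}, {replacement})")
    return "NC"


def cmp_profile(tess: Tessellation, potential: FourBodyPotential,
                per_site: bool = True) -> CmpProfile:
    """CMP per position: mean residual score of all 19 substitutions.

    ``per_site`` substitutes at the single flat position (the convention
    for reporting per-position CMP in multimers); with ``per_site=False``
    each substitution is applied at every chain copy of the position's
    author number, as variants are.
    """
    n = len(tess.structure)
    cmp_scores = np.zeros(n)
    c_scores = np.zeros(n)
    nc_scores = np.zeros(n)
    for site in tess.structure.sites:
        residuals_c: list[float] = []
        residuals_nc: list[float] = []
        for replacement in AMINO_ACIDS:
            if replacement == site.res_type:
                continue
            variant = VariantSpec(site.res_type, site.author_resnum, replacement)
            try:
                prof = residual_profile(tess, potential, variant,
                                        chain=site.chain_id if per_site else None)
            except MutagenesisError as exc:
                raise MutagenesisError(
                    f"CMP at position {tess.structure.label(site.flat_index)}: {exc}"
                ) from exc
            if substitution_class(site.res_type, replacement) == "C":
                residuals_c.append(prof.residual_score)
            else:
                residuals_nc.append(prof.residual_score)
        all_res = residuals_c + residuals_nc
        cmp_scores[site.flat_index] = np.mean(all_res)
        c_scores[site.flat_index] = np.mean(residuals_c) if residuals_c else np.nan
        nc_scores[site.flat_index] = np.mean(residuals_nc) if residuals_nc else np.nan
    return CmpProfile(cmp=cmp_scores, c_cmp=c_scores, nc_cmp=nc_scores)
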