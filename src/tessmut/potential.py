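"""The four-body knowledge-based statistical potential.

Every retained tetrahedron of a structure tessellation presents an
unordered quadruplet of residue types at its vertices.  Over a training
set of tessellated structures, the observed relative frequency f of each
quadruplet is compared with the rate p expected by chance under a
multinomial reference distribution built from the training-set residue
composition; the inverted-Boltzmann score

    s = −log(f / p)

over all quadruplet types defines the potential.  For the standard
20-letter alphabet there are C(23, 4) = 8855 distinct quadruplet types
(multisets of size 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping

from .structure_io import AMINO_ACIDS
from .tessellation import Tessellation


class PotentialError(ValueError):
    """Raised for invalid potential construction or use."""


class UnscoredQuadrupletError(PotentialError):
    """A quadruplet without an observed count (and no pseudocount) was scored."""


def quadruplet_key(letters: Iterable[str]) -> str:
    """Canonical key for an unordered residue quadruplet: ascending letters."""
    key = "".join(sorted(letters))
    if len(key) != 4:
        raise PotentialError(f"quadruplet needs exactly 4 letters, got {key!r}")
    return key


def enumerate_quadruplets(alphabet: str = AMINO_ACIDS) -> list[str]:
    """All multisets of 4 letters over ``alphabet``, lexicographic order."""
    if not alphabet:
        raise PotentialError("alphabet must be non-empty")
    return ["".join(c) for c in combinations_with_replacement(sorted(alphabet), 4)]


def multinomial_rate(key: str, composition: Mapping[str, float]) -> float:
    """Chance rate of a quadruplet under the multinomial reference.

        p = 4! / ∏ t_n!  ·  ∏ a_n^{t_n}

    where a_n is the proportion of residue type n in the training set and
    t_n its multiplicity in the quadruplet.
    """
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise PotentialError(f"composition sums to {total!r}, expected 1")
    counts: dict[str, int] = {}
    for letter in key:
        if letter not in composition:
            raise PotentialError(f"letter {letter!r} missing from composition")
        counts[letter] = counts.get(letter, 0) + 1
    rate = math.factorial(4)
    for letter, t in counts.items():
        rate /= math.factorial(t)
        rate *= composition[letter] ** t
    return rate


@dataclass
class FourBodyPotential:
    """Quadruplet score table with its frequency and rate components.

    ``scores[key]`` is ``None`` for quadruplets that were never observed
    and carry no pseudocount — scoring such a key raises, it is never a
    silent zero.  A table loaded from text carries only scores.
    """

    alphabet: str
    scores: dict[str, float | None]
    composition: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    f: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    log_base: float = math.e
    pseudocount: float = 0.0

    def score(self, key: str) -> float:
        try:
            value = self.scores[key]
        except KeyError:
            raise UnscoredQuadrupletError(f"quadruplet {key!r} not in potential") from None
        if value is None:
            raise UnscoredQuadrupletError(
                f"quadruplet {key!r} was never observed in training "
                "(use a pseudocount to score unobserved quadruplets)"
            )
        return value

    def is_scored(self, key: str) -> bool:
        return self.scores.get(key) is not None

    @property
    def n_unscored(self) -> int:
        return sum(1 for v in self.scores.values() if v is None)


def residue_composition(tessellations: Iterable[Tessellation]) -> dict[str, float]:
    """Pooled residue-type proportions over the training structures."""
    counts: dict[str, int] = {}
    total = 0
    for tess in tessellations:
        for site in tess.structure.sites:
            counts[site.res_type] = counts.get(site.res_type, 0) + 1
            total += 1
    if total == 0:
        raise PotentialError("no residues in training set")
    return {letter: n / total for letter, n in counts.items()}


def derive_potential(tessellations: list[Tessellation],
                     alphabet: str = AMINO_ACIDS,
                     log_base: float = math.e,
                     pseudocount: float = 0.0) -> FourBodyPotential:
    """Derive the four-body potential from training tessellations.

    Each retained tetrahedron increments its quadruplet count once.  The
    composition a_n is pooled over all residues of the training
    structures.  With ``pseudocount`` q > 0, frequencies are smoothed as
    (count + q) / Σ(count + q) so every quadruplet gets a finite score;
    with q = 0 unobserved quadruplets are marked unscored.
    """
    if not tessellations:
        raise PotentialError("at least one training tessellation required")
    if pseudocount < 0:
        raise PotentialError("pseudocount must be >= 0")
    keys = enumerate_quadruplets(alphabet)
    counts = {k: 0 for k in keys}
    total = 0
    for tess in tessellations:
        seq = tess.structure.sequence
        for tet in tess.tetrahedra:
            key = quadruplet_key(seq[v] for v in tet.vertex_ids)
            if key not in counts:
                raise PotentialError(f"residue quadruplet {key!r} outside alphabet")
            counts[key] += 1
            total += 1
    if total == 0:
        raise PotentialError("training tessellations contain zero retained tetrahedra")

    composition = residue_composition(tessellations)
    composition = {letter: composition.get(letter, 0.0) for letter in sorted(alphabet)}
    smoothed_total = total + pseudocount * len(keys)
    log_div = math.log(log_base)
    f: dict[str, float] = {}
    p: dict[str, float] = {}
    scores: dict[str, float | None] = {}
    for key in keys:
        f[key] = counts[key] / total
        p[key] = multinomial_rate(key, composition)
        smoothed_f = (counts[key] + pseudocount) / smoothed_total
        if smoothed_f == 0.0:
            scores[key] = None
        elif p[key] == 0.0:
            # letter absent from training composition but present via pseudocount
            scores[key] = None
        else:
            scores[key] = -math.log(smoothed_f / p[key]) / log_div
    return FourBodyPotential(alphabet="".join(sorted(alphabet)), scores=scores,
                             composition=composition, counts=counts, f=f, p=p,
                             log_base=log_base, pseudocount=pseudocount)


def write_potential(potential: FourBodyPotential) -> str:
    """Serialize a potential as two-column text: ``QUAD score`` per line.

    Unscored quadruplets are written with the marker ``NA``.
    """
    lines = []
    for key in sorted(potential.scores):
        value = potential.scores[key]
        lines.append(f"{key}\t{'NA' if value is None else format(value, '.6g')}")
    return "\n".join(lines) + "\n"


def read_potential(table_text: str, alphabet: str = AMINO_ACIDS) -> FourBodyPotential:
    """Parse a two-column quadruplet score table.

    Accepts the ``potential1417cut12.txt`` dialect: one quadruplet (four
    ascending letters) and one score per line, whitespace-delimited.
    ``NA`` marks an unscored quadruplet.  Malformed lines, unknown
    letters, unsorted keys and duplicates are rejected with the line
    number.
    """
    scores: dict[str, float | None] = {}
    for lineno, raw in enumerate(table_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise PotentialError(f"line {lineno}: expected 'QUAD score', got {raw!r}")
        key, value_text = parts
        if len(key) != 4 or any(c not in alphabet for c in key):
            raise PotentialError(f"line {lineno}: bad quadruplet {key!r}")
        if "".join(sorted(key)) != key:
            raise PotentialError(f"line {lineno}: quadruplet {key!r} not in ascending order")
        if key in scores:
            raise PotentialError(f"line {lineno}: duplicate quadruplet {key!r}")
        if value_text.upper() == "NA":
            scores[key] = None
        else:
            try:
                scores[key] = float(value_text)
            except ValueError:
                raise PotentialError(f"line {lineno}: bad score {value_text!r}") from None
    if not scores:
        raise PotentialError("empty potential table")
    return FourBodyPotential(alphabet="".join(sorted(alphabet)), scores=scores)
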