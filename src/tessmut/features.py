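"""Variant feature vectors and labeled dataset assembly.

Two encodings of a variant are supported:

* the 27-attribute vector centred on the mutated position and its six
  closest tessellation neighbors (identities, EP scores, sequence
  separations, tetrahedron geometry means, depth, surface contacts,
  secondary structure);
* the residual-profile encoding, whose inputs are the EP scores at every
  position of one chain (optionally plus a 3-attribute variant ID).

Activity categories follow the log2(effect size) conventions: Superior
(>0), Similar ([−2, 0]), Inferior (<−2); the binary split is unaffected
(≥−2) versus affected (<−2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mutagenesis import (MutagenesisError, ResidualProfile, VariantSpec,
                          parse_variant, residual_profile)
from .potential import FourBodyPotential
from .tessellation import Tessellation, classify_depth

log = logging.getLogger(__name__)

ACTIVITY_THRESHOLD = -2.0  # binary unaffected/affected cutoff on log2(effect size)

#: Column order of the 27 input attributes (plus metadata and output).
FEATURE27_COLUMNS = (
    ["position", "native", "replacement", "ep_mut"]
    + [f"seq_sep_{i}" for i in range(1, 7)]
    + [f"nbr_res_{i}" for i in range(1, 7)]
    + [f"nbr_ep_{i}" for i in range(1, 7)]
    + ["mean_volume", "mean_tetrahedrality", "depth", "surface_contacts",
       "secondary_structure"]
)

CATEGORICAL_COLUMNS = (
    ["native", "replacement", "depth", "secondary_structure"]
    + [f"nbr_res_{i}" for i in range(1, 7)]
)


class FeatureError(ValueError):
    """Raised when a feature vector cannot be constructed."""


class InsufficientNeighborsError(FeatureError):
    """The mutated position has fewer than six tessellation neighbors."""


def classify_activity(log2_effect: float,
                      threshold: float = ACTIVITY_THRESHOLD) -> dict[str, str]:
    """Three-way and binary activity categories of a log2(effect size)."""
    if log2_effect > 0.0:
        cat3 = "Superior"
    elif log2_effect >= threshold:
        cat3 = "Similar"
    else:
        cat3 = "Inferior"
    cat2 = "unaffected" if log2_effect >= threshold else "affected"
    return {"category3": cat3, "category2": cat2}


@dataclass(frozen=True)
class ActivityRecord:
    variant: VariantSpec
    log2_effect: float
    category3: str
    category2: str


def read_activity_table(text: str) -> list[ActivityRecord]:
    """Parse a ``variant<TAB>log2_effect`` table (variant syntax ``C14E``)."""
    records: list[ActivityRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise FeatureError(f"line {lineno}: expected 'variant<TAB>log2', got {raw!r}")
        variant = parse_variant(parts[0])
        if str(variant) in seen:
            raise FeatureError(f"line {lineno}: duplicate variant {variant}")
        seen.add(str(variant))
        try:
            log2 = float(parts[1])
        except ValueError:
            raise FeatureError(f"line {lineno}: bad log2 value {parts[1]!r}") from None
        records.append(ActivityRecord(variant=variant, log2_effect=log2,
                                      **classify_activity(log2)))
    return records


def six_nearest_neighbors(tess: Tessellation, pos: int) -> list[int]:
    """The six retained-edge neighbors closest in C-alpha distance.

    Ordered by ascending distance, ties broken by lower flat index.
    Raises :class:`InsufficientNeighborsError` when fewer than six
    neighbors exist (such positions are excluded from 27-attribute
    datasets, as position 44 of Gal4 is).
    """
    neighbors = tess.neighbor_positions(pos)
    if len(neighbors) < 6:
        raise InsufficientNeighborsError(
            f"position {pos} has only {len(neighbors)} neighbors (6 required)"
        )
    coords = tess.structure.coords
    ranked = sorted(neighbors,
                    key=lambda n: (float(np.linalg.norm(coords[n] - coords[pos])), n))
    return ranked[:6]


def build_feature_vector_27(variant: VariantSpec, tess: Tessellation,
                            potential: FourBodyPotential,
                            ss_map: dict[tuple[str, int], str] | None = None,
                            site_index: int | None = None,
                            profile: ResidualProfile | None = None,
                            depth: tuple[dict[int, str], dict[int, int]] | None = None,
                            ) -> dict:
    """Assemble the 27-attribute vector for one chain copy of a variant.

    ``site_index`` selects the chain copy (default: the only copy);
    ``profile``/``depth`` allow reuse of precomputed results when
    building whole datasets.
    """
    if profile is None:
        profile = residual_profile(tess, potential, variant)
    if site_index is None:
        if len(profile.mutated_sites) != 1:
            raise FeatureError("site_index required for multimeric structures")
        site_index = profile.mutated_sites[0]
    if site_index not in profile.mutated_sites:
        raise FeatureError(f"site {site_index} is not a mutated site of {variant}")
    neighbors = six_nearest_neighbors(tess, site_index)
    if depth is None:
        depth = classify_depth(tess)
    classes, contacts = depth
    incident = tess.incident_tetrahedra(site_index)
    site = tess.structure.sites[site_index]
    ss = "C"
    if ss_map:
        ss = ss_map.get((site.chain_id, site.author_resnum), "C")
    row = {
        "position": variant.position,
        "native": variant.native,
        "replacement": variant.replacement,
        "ep_mut": float(profile.ep[site_index]),
    }
    for i, n in enumerate(neighbors, start=1):
        nsite = tess.structure.sites[n]
        row[f"seq_sep_{i}"] = nsite.author_resnum - site.author_resnum
    for i, n in enumerate(neighbors, start=1):
        row[f"nbr_res_{i}"] = tess.structure.sites[n].res_type
    for i, n in enumerate(neighbors, start=1):
        row[f"nbr_ep_{i}"] = float(profile.ep[n])
    row["mean_volume"] = float(np.mean([t.volume for t in incident])) if incident else 0.0
    row["mean_tetrahedrality"] = (
        float(np.mean([t.tetrahedrality for t in incident])) if incident else 0.0
    )
    row["depth"] = classes[site_index]
    row["surface_contacts"] = contacts[site_index]
    row["secondary_structure"] = ss
    return row


def build_profile_feature_vectors(variant: VariantSpec, tess: Tessellation,
                                  potential: FourBodyPotential,
                                  include_id: bool = False,
                                  profile: ResidualProfile | None = None) -> list[dict]:
    """Per-chain residual-profile vectors for one variant.

    The full EP vector of the (multimeric) tessellation is split per
    chain; each chain contributes one vector whose components are the EP
    scores at that chain's positions in chain order.  ``include_id``
    appends wild-type residue, position number and replacement residue.
    """
    if profile is None:
        profile = residual_profile(tess, potential, variant)
    chains = tess.structure.chain_order
    lengths = {c: len(tess.structure.chain(c)) for c in chains}
    if len(set(lengths.values())) != 1:
        raise FeatureError(f"chain lengths unequal: {lengths}")
    length = next(iter(lengths.values()))
    rows = []
    for chain_id in chains:
        sites = tess.structure.chain(chain_id)
        row = {"chain": chain_id}
        for k, s in enumerate(sites, start=1):
            row[f"ep_{k}"] = float(profile.ep[s.flat_index])
        if include_id:
            row["native"] = variant.native
            row["position"] = variant.position
            row["replacement"] = variant.replacement
        rows.append(row)
    assert all(len(r) == length + 1 + (3 if include_id else 0) for r in rows)
    return rows


@dataclass
class VariantDataset:
    """Labeled feature vectors ready for model training."""

    frame: pd.DataFrame
    mode: str
    task: str
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def feature_columns(self) -> list[str]:
        meta = {"variant", "chain", "log2_effect", "activity_class"}
        return [c for c in self.frame.columns if c not in meta]

    @property
    def output_column(self) -> str:
        return "log2_effect" if self.task == "regression" else "activity_class"


MODES = ("monomer-27", "dimer-27", "profile-EP", "profile-EP+ID")


def assemble_dataset(records: list[ActivityRecord], tess: Tessellation,
                     potential: FourBodyPotential, mode: str, task: str,
                     ss_map: dict[tuple[str, int], str] | None = None) -> VariantDataset:
    """Build a labeled dataset in one of the four encodings.

    27-attribute modes drop variants whose mutated position has fewer
    than six neighbors, recording them in the exclusion manifest;
    profile modes represent every variant.  ``dimer-27`` and the profile
    modes emit one row per chain copy, sharing the output attribute.
    """
    if mode not in MODES:
        raise FeatureError(f"unknown mode {mode!r}; expected one of {MODES}")
    if task not in ("classification", "regression"):
        raise FeatureError(f"unknown task {task!r}")
    if not records:
        raise FeatureError("no activity records supplied")
    seen: set[str] = set()
    for r in records:
        if str(r.variant) in seen:
            raise FeatureError(f"duplicate variant {r.variant}")
        seen.add(str(r.variant))

    depth = classify_depth(tess) if mode.endswith("27") else None
    rows: list[dict] = []
    excluded: list[tuple[str, str]] = []
    for record in records:
        variant = record.variant
        try:
            profile = residual_profile(tess, potential, variant)
        except MutagenesisError as exc:
            raise FeatureError(f"variant {variant}: {exc}") from exc
        try:
            if mode in ("monomer-27", "dimer-27"):
                sites = profile.mutated_sites
                if mode == "monomer-27" and len(sites) != 1:
                    raise FeatureError(
                        f"monomer-27 mode requires single-chain structures; "
                        f"{variant} maps to {len(sites)} sites"
                    )
                variant_rows = [
                    build_feature_vector_27(variant, tess, potential, ss_map=ss_map,
                                            site_index=s, profile=profile, depth=depth)
                    for s in sites
                ]
                for s, row in zip(sites, variant_rows):
                    row["chain"] = tess.structure.sites[s].chain_id
            else:
                variant_rows = build_profile_feature_vectors(
                    variant, tess, potential,
                    include_id=mode.endswith("+ID"), profile=profile)
        except InsufficientNeighborsError as exc:
            excluded.append((str(variant), str(exc)))
            log.info("excluding %s: %s", variant, exc)
            continue
        for row in variant_rows:
            row["variant"] = str(variant)
            row["log2_effect"] = record.log2_effect
            row["activity_class"] = record.category2
            rows.append(row)
    if not rows:
        raise FeatureError("no feature vectors could be built (all variants excluded)")
    frame = pd.DataFrame(rows)
    lead = ["variant", "chain"] if "chain" in frame.columns else ["variant"]
    ordered = lead + [c for c in frame.columns if c not in lead]
    return VariantDataset(frame=frame[ordered], mode=mode, task=task, excluded=excluded)


def write_arff(dataset: VariantDataset, relation: str = "tessmut") -> str:
    """Render a dataset in ARFF for Weka-ecosystem interoperability."""
    frame = dataset.frame
    meta = {"variant", "chain"}
    columns = [c for c in frame.columns if c not in meta]
    lines = [f"@RELATION {relation}", ""]
    for col in columns:
        series = frame[col]
        if series.dtype == object:
            values = ",".join(sorted(map(str, series.unique())))
            lines.append(f"@ATTRIBUTE {col} {{{values}}}")
        else:
            lines.append(f"@ATTRIBUTE {col} NUMERIC")
    lines += ["", "@DATA"]
    for _, row in frame.iterrows():
        lines.append(",".join(str(row[c]) for c in columns))
    return "\n".join(lines) + "\n"
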