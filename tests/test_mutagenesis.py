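"""Scoring algebra: total potential, RES/EP profiles, residuals, CMP.

The independent oracle for residual scoring is an exhaustive rescore:
relabel the sequence, re-score every tetrahedron of the *same*
tessellation, and difference the totals.  The incremental implementation
must agree exactly.
"""

import numpy as np
import pytest

from tessmut.mutagenesis import (MutagenesisError, VariantSpec, cmp_profile,
                                 parse_variant, residual_profile,
                                 residue_environment_profile,
                                 substitution_class, total_potential)
from tessmut.potential import FourBodyPotential, quadruplet_key
from tessmut.structure_io import AMINO_ACIDS
from tessmut.synthetic import SyntheticSpec, random_variants, synthetic_structure
from tessmut.tessellation import Tessellation, tessellate
from tests.conftest import make_structure


def exhaustive_rescore(tess: Tessellation, potential, sequence) -> float:
    """Oracle: total potential of a relabeled structure, all tetrahedra."""
    return sum(
        potential.score(quadruplet_key(sequence[v] for v in t.vertex_ids))
        for t in tess.tetrahedra
    )


def mutate_sequence(structure, variant: VariantSpec) -> list[str]:
    seq = list(structure.sequence)
    for site in structure.sites_at_label(variant.position):
        seq[site.flat_index] = variant.replacement
    return seq


def constant_potential(value: float) -> FourBodyPotential:
    from tessmut.potential import enumerate_quadruplets
    return FourBodyPotential(alphabet=AMINO_ACIDS,
                             scores={k: value for k in enumerate_quadruplets()})


def test_single_tetrahedron_total_and_res(single_tetra_structure):
    tess = tessellate(single_tetra_structure)
    pot = constant_potential(2.0)
    assert total_potential(tess, pot) == pytest.approx(2.0)
    profile = residue_environment_profile(tess, pot)
    assert np.allclose(profile.res, 2.0)


def test_res_sums_to_four_times_total(globule_tess, toy_potential):
    profile = residue_environment_profile(globule_tess, toy_potential)
    assert profile.res.sum() == pytest.approx(4.0 * profile.total_potential)
    assert profile.total_potential == pytest.approx(
        total_potential(globule_tess, toy_potential))


def test_total_matches_independent_enumeration(globule_tess, toy_potential):
    oracle = exhaustive_rescore(globule_tess, toy_potential,
                                globule_tess.structure.sequence)
    assert total_potential(globule_tess, toy_potential) == pytest.approx(oracle)


def test_unscored_key_raises_naming_quadruplet(globule_tess):
    from tessmut.potential import derive_potential
    sparse = derive_potential([globule_tess])  # pseudocount 0: others unscored
    site = globule_tess.structure.sites[5]
    repl = next(a for a in AMINO_ACIDS if a != site.res_type)
    variant = VariantSpec(site.res_type, site.author_resnum, repl)
    with pytest.raises(MutagenesisError):
        residual_profile(globule_tess, sparse, variant)


def test_empty_tessellation_rejected(single_tetra_structure):
    tess = tessellate(single_tetra_structure, edge_cutoff=1.0)  # filters all
    with pytest.raises(MutagenesisError, match="zero retained"):
        total_potential(tess, constant_potential(1.0))


@pytest.mark.parametrize("variant_index", [0, 7, 23])
def test_incremental_residual_matches_full_rescore(globule_tess, toy_potential,
                                                   variant_index):
    variants = random_variants(globule_tess.structure, 30, seed=5)
    variant = variants[variant_index]
    prof = residual_profile(globule_tess, toy_potential, variant)
    native_total = exhaustive_rescore(globule_tess, toy_potential,
                                      globule_tess.structure.sequence)
    mutant_total = exhaustive_rescore(
        globule_tess, toy_potential,
        mutate_sequence(globule_tess.structure, variant))
    assert prof.residual_score == pytest.approx(mutant_total - native_total)
    assert prof.ep.sum() == pytest.approx(4.0 * prof.residual_score)


def test_monomer_ep_at_mutated_position_equals_residual(globule_tess, toy_potential):
    for variant in random_variants(globule_tess.structure, 10, seed=9):
        prof = residual_profile(globule_tess, toy_potential, variant)
        (site,) = prof.mutated_sites
        assert prof.ep[site] == pytest.approx(prof.residual_score)


def test_ep_locality_support_is_mutated_site_plus_neighbors(globule_tess,
                                                            toy_potential):
    for variant in random_variants(globule_tess.structure, 15, seed=13):
        prof = residual_profile(globule_tess, toy_potential, variant)
        (site,) = prof.mutated_sites
        allowed = globule_tess.neighbor_positions(site) | {site}
        assert set(prof.nonzero_positions) <= allowed


def test_identity_substitution_is_rejected_but_zero_by_algebra(globule_tess,
                                                               toy_potential):
    site = globule_tess.structure.sites[3]
    with pytest.raises(MutagenesisError, match="not a variant"):
        VariantSpec(site.res_type, site.author_resnum, site.res_type)
    # the algebraic identity-substitution case: replacement equal to native
    # forced through the rescoring path gives an all-zero profile
    native_total = exhaustive_rescore(globule_tess, toy_potential,
                                      globule_tess.structure.sequence)
    same = exhaustive_rescore(globule_tess, toy_potential,
                              list(globule_tess.structure.sequence))
    assert same == pytest.approx(native_total)


def test_native_mismatch_and_unknown_position_rejected(globule_tess, toy_potential):
    site = globule_tess.structure.sites[0]
    wrong_native = next(a for a in AMINO_ACIDS if a != site.res_type)
    with pytest.raises(MutagenesisError, match="native mismatch"):
        residual_profile(globule_tess, toy_potential,
                         VariantSpec(wrong_native, site.author_resnum, "W"
                                     if wrong_native != "W" else "Y"))
    with pytest.raises(MutagenesisError, match="not found"):
        residual_profile(globule_tess, toy_potential, VariantSpec("A", 9999, "W"))


def test_antisymmetry_forward_and_back(globule_tess, toy_potential):
    variant = random_variants(globule_tess.structure, 5, seed=21)[0]
    forward = residual_profile(globule_tess, toy_potential, variant)
    # relabel the structure to the mutant and apply the reverse substitution
    mutant_seq = mutate_sequence(globule_tess.structure, variant)
    mutant_structure = make_structure(globule_tess.structure.coords,
                                      "".join(mutant_seq))
    mutant_tess = tessellate(mutant_structure)
    back = residual_profile(
        mutant_tess, toy_potential,
        VariantSpec(variant.replacement, variant.position, variant.native))
    assert back.residual_score == pytest.approx(-forward.residual_score)


def test_dimer_variant_mutates_both_chains(dimer_tess, toy_potential):
    site = dimer_tess.structure.sites[10]
    repl = next(a for a in AMINO_ACIDS if a != site.res_type)
    variant = VariantSpec(site.res_type, site.author_resnum, repl)
    prof = residual_profile(dimer_tess, toy_potential, variant)
    assert len(prof.mutated_sites) == 2
    chains = {dimer_tess.structure.sites[s].chain_id for s in prof.mutated_sites}
    assert chains == {"A", "B"}
    assert prof.ep.sum() == pytest.approx(4.0 * prof.residual_score)
    # oracle: exhaustive rescore of the doubly relabeled dimer
    native_total = exhaustive_rescore(dimer_tess, toy_potential,
                                      dimer_tess.structure.sequence)
    mutant_total = exhaustive_rescore(
        dimer_tess, toy_potential, mutate_sequence(dimer_tess.structure, variant))
    assert prof.residual_score == pytest.approx(mutant_total - native_total)


def test_single_chain_option_restricts_mutation(dimer_tess, toy_potential):
    site = dimer_tess.structure.sites[4]
    repl = next(a for a in AMINO_ACIDS if a != site.res_type)
    variant = VariantSpec(site.res_type, site.author_resnum, repl)
    prof = residual_profile(dimer_tess, toy_potential, variant, chain="B")
    assert len(prof.mutated_sites) == 1
    assert dimer_tess.structure.sites[prof.mutated_sites[0]].chain_id == "B"


def test_cmp_zero_under_constant_potential(single_tetra_structure):
    tess = tessellate(single_tetra_structure)
    prof = cmp_profile(tess, constant_potential(1.5))
    assert np.allclose(prof.cmp, 0.0)


def test_cmp_equals_mean_of_19_explicit_residuals(globule_tess, toy_potential):
    prof = cmp_profile(globule_tess, toy_potential)
    for flat in (2, 17, 40):
        site = globule_tess.structure.sites[flat]
        residuals = [
            residual_profile(globule_tess, toy_potential,
                             VariantSpec(site.res_type, site.author_resnum, r),
                             chain=site.chain_id).residual_score
            for r in AMINO_ACIDS if r != site.res_type
        ]
        assert len(residuals) == 19
        assert prof.cmp[flat] == pytest.approx(np.mean(residuals))
        # All-mean decomposes into the count-weighted C/NC submeans
        n_c = sum(1 for r in AMINO_ACIDS if r != site.res_type
                  and substitution_class(site.res_type, r) == "C")
        if n_c == 0:  # native cysteine: no conservative substitutions exist
            assert np.isnan(prof.c_cmp[flat])
            assert prof.cmp[flat] == pytest.approx(prof.nc_cmp[flat])
        else:
            weighted = (n_c * prof.c_cmp[flat] + (19 - n_c) * prof.nc_cmp[flat]) / 19
            assert prof.cmp[flat] == pytest.approx(weighted)


@pytest.mark.parametrize("native,replacement,expected", [
    ("L", "I", "C"),   # same apolar cluster
    ("L", "D", "NC"),
    ("C", "A", "NC"),  # cysteine is a singleton cluster
    ("C", "S", "NC"),
    ("D", "E", "C"),
    ("R", "K", "C"),
    ("F", "W", "C"),
    ("A", "G", "C"),
    ("K", "E", "NC"),
])
def test_substitution_classes(native, replacement, expected):
    assert substitution_class(native, replacement) == expected


def test_substitution_class_rejects_identity():
    with pytest.raises(MutagenesisError):
        substitution_class("A", "A")


def test_parse_variant_syntax():
    v = parse_variant("C14E")
    assert (v.native, v.position, v.replacement) == ("C", 14, "E")
    with pytest.raises(MutagenesisError):
        parse_variant("14E")
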