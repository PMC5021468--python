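import logging

import numpy as np
import pytest

from saltnet import (
    DomainDefinition,
    IonPairParams,
    ResidueId,
    Structure,
    active_site_check,
    build_assembly,
    build_networks,
    classify_pairs,
    default_domains,
    find_ion_pairs,
    pair_counts,
)
from saltnet.ion_pairs import pairs_to_dataframe
from saltnet.synthetic import (
    FixtureSpec,
    PlantedPair,
    brute_force_ion_pairs,
    default_dimer_transform,
    make_dimer_fixture,
    rotation_about_z,
)

from conftest import make_residue


def random_fixture_spec(seed: int) -> FixtureSpec:
    """Randomized planted-contact dimer used by the oracle-equivalence check."""
    rng = np.random.default_rng(seed)
    n_res = int(rng.integers(60, 100))
    positions = list(range(5, n_res - 2, 6))
    n_pairs = min(int(rng.integers(2, 7)), len(positions) // 2)
    positions = positions[: 2 * n_pairs]
    rng.shuffle(positions)
    planted = []
    pos_names = ["ARG", "LYS"]
    neg_names = ["GLU", "ASP"]
    for k in range(n_pairs):
        planted.append(PlantedPair(
            pos_index=positions[2 * k],
            neg_index=positions[2 * k + 1],
            distance=float(rng.uniform(2.6, 5.4)),
            pos_name=pos_names[k % 2],
            neg_name=neg_names[k % 2],
        ))
    angle = float(rng.uniform(0, 360))
    shift = rng.uniform(25, 60, size=3)
    return FixtureSpec(
        n_residues=n_res,
        planted_pairs=tuple(planted),
        dimer_transform=(rotation_about_z(angle), shift),
        noise_sd=float(rng.uniform(0, 0.05)),
        seed=seed,
    )


def as_key_set(pairs):
    return {
        ((p.res_a.chain_id, p.res_a.seq_id), (p.res_b.chain_id, p.res_b.seq_id))
        for p in pairs
    }


class TestDetection:
    def test_planted_contacts_below_cutoff_detected(self, planted_dimer):
        _, structure, truth = planted_dimer
        pairs = find_ion_pairs(structure)
        expected = {
            ((p["pos"][0], p["pos"][1]), (p["neg"][0], p["neg"][1]))
            for p in truth.expected_ion_pairs
        }
        assert as_key_set(pairs) == expected
        # the 4.5-A planted pair must be absent
        assert not any(p.res_a.seq_id == 45 for p in pairs)

    def test_cutoff_is_inclusive_at_exact_boundary(self):
        s = Structure(source_id="boundary")
        s.chains["A"] = [
            make_residue("A", 1, "LYS", {"CA": (0, -2, 0), "NZ": (0, 0, 0)}),
            make_residue("A", 8, "GLU", {"CA": (4, 2, 0), "OE1": (4.0, 0, 0),
                                         "OE2": (5.5, 0, 0)}),
            make_residue("A", 15, "ASP", {"CA": (9, 2, 0), "OD1": (0, 4.000001, 0),
                                          "OD2": (0, 5.5, 0)}),
        ]
        pairs = find_ion_pairs(s)
        assert as_key_set(pairs) == {(("A", 1), ("A", 8))}
        assert pairs[0].min_distance == pytest.approx(4.0, abs=0)

    def test_multiple_atom_contacts_count_once(self):
        # three guanidinium atoms all touching both carboxylate oxygens
        s = Structure(source_id="multi-contact")
        s.chains["A"] = [
            make_residue("A", 1, "ARG", {"CA": (0, -3, 0), "NE": (0, 0, 0),
                                         "NH1": (0.8, 0, 0), "NH2": (-0.8, 0, 0)}),
            make_residue("A", 9, "GLU", {"CA": (0, 5, 0), "OE1": (0, 2.8, 0),
                                         "OE2": (0.7, 3.1, 0)}),
        ]
        pairs = find_ion_pairs(s)
        assert len(pairs) == 1
        assert pairs[0].closest_atom_pair == ("NE", "OE1")
        assert pairs[0].min_distance == pytest.approx(2.8)

    def test_no_charged_residues_gives_empty_list(self):
        s = Structure(source_id="bland")
        s.chains["A"] = [make_residue("A", i, "ALA", {"CA": (3.8 * i, 0, 0)})
                        for i in range(1, 8)]
        assert find_ion_pairs(s) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        structure, _ = make_dimer_fixture(random_fixture_spec(seed))
        detected = find_ion_pairs(structure)
        oracle = brute_force_ion_pairs(structure, cutoff=4.0)
        assert as_key_set(detected) == {
            ((p["pos"][0], p["pos"][1]), (p["neg"][0], p["neg"][1]))
            for p in oracle
        }
        by_key = {((p["pos"][0], p["pos"][1]), (p["neg"][0], p["neg"][1])): p["distance"]
                  for p in oracle}
        for pair in detected:
            key = ((pair.res_a.chain_id, pair.res_a.seq_id),
                   (pair.res_b.chain_id, pair.res_b.seq_id))
            assert pair.min_distance == pytest.approx(by_key[key], abs=1e-9)

    def test_chain_relabeling_only_permutes_pairs(self, planted_dimer):
        _, structure, _ = planted_dimer
        swapped = structure.copy()
        swapped.chains = {"B": swapped.chains["A"], "A": swapped.chains["B"]}
        for cid, residues in swapped.chains.items():
            for r in residues:
                r.chain_id = cid
        orig = find_ion_pairs(structure)
        after = find_ion_pairs(swapped)
        assert len(orig) == len(after)
        relabel = {"A": "B", "B": "A"}
        assert as_key_set(after) == {
            ((relabel[a[0]], a[1]), (relabel[b[0]], b[1])) for a, b in as_key_set(orig)
        }

    @pytest.mark.parametrize("seed", [3, 14])
    def test_count_monotone_in_cutoff(self, seed):
        structure, _ = make_dimer_fixture(random_fixture_spec(seed))
        cutoffs = [0.1, 1.0, 2.5, 3.5, 4.0, 5.0, 7.0]
        counts = [len(find_ion_pairs(structure, IonPairParams(cutoff=c)))
                  for c in cutoffs]
        assert counts == sorted(counts)
        assert counts[0] == 0

    def test_histidine_toggle(self):
        s = Structure(source_id="his-toy")
        s.chains["A"] = [
            make_residue("A", 1, "HIS", {"CA": (0, -3, 0), "ND1": (0, 0, 0),
                                         "NE2": (1.1, 0.7, 0)}),
            make_residue("A", 9, "ASP", {"CA": (0, 6, 0), "OD1": (0, 3.0, 0),
                                         "OD2": (0.9, 3.4, 0)}),
        ]
        assert find_ion_pairs(s) == []
        with_his = find_ion_pairs(s, IonPairParams(include_histidine=True))
        assert len(with_his) == 1
        assert with_his[0].res_a.name == "HIS"

    def test_histidine_never_reported_when_excluded(self):
        for seed in range(5):
            structure, _ = make_dimer_fixture(random_fixture_spec(seed))
            for pair in find_ion_pairs(structure):
                assert "HIS" not in (pair.res_a.name, pair.res_b.name)

    def test_residue_missing_charged_atoms_is_skipped(self, caplog):
        s = Structure(source_id="disordered")
        s.chains["A"] = [
            # lysine side chain disordered beyond CB: no NZ modeled
            make_residue("A", 1, "LYS", {"CA": (0, 0, 0), "CB": (0, 1.5, 0)}),
            make_residue("A", 9, "GLU", {"CA": (0, 5, 0), "OE1": (0, 2.0, 0),
                                         "OE2": (0, 3.2, 0)}),
        ]
        with caplog.at_level(logging.WARNING, logger="saltnet"):
            pairs = find_ion_pairs(s)
        assert pairs == []
        assert any("no charged side-chain atoms" in r.message for r in caplog.records)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            IonPairParams(cutoff=0.0)
        with pytest.raises(ValueError):
            IonPairParams(positive_residues=frozenset({"ARG", "GLU"}),
                          negative_residues=frozenset({"GLU"}))


class TestClassification:
    def test_single_chain_is_all_intrasubunit(self, planted_dimer):
        _, structure, _ = planted_dimer
        mono = Structure(chains={"A": structure.chains["A"]},
                        seqres=dict(structure.seqres), source_id="mono")
        pairs = classify_pairs(find_ion_pairs(mono), default_domains(mono))
        assert pairs and all(p.span == "intrasubunit" for p in pairs)

    def test_interface_pair_is_intersubunit_and_interterminal(self, interface_dimer):
        pairs = classify_pairs(find_ion_pairs(interface_dimer),
                               default_domains(interface_dimer))
        inter = [p for p in pairs if p.span == "intersubunit"]
        assert len(inter) == 1
        pair = inter[0]
        assert (pair.res_a.name, pair.res_a.seq_id) == ("ARG", 58)
        assert (pair.res_b.name, pair.res_b.seq_id) == ("GLU", 8)
        assert pair.regions == ("c_terminal", "n_terminal")
        assert pair.is_interterminal
        counts = pair_counts(pairs)
        assert counts["intersubunit"] == 1
        assert counts["interterminal"] == 1
        assert counts["intrasubunit"] == counts["total"] - 1

    def test_residue_outside_intervals_is_unassigned(self, interface_dimer, caplog):
        narrow = {cid: DomainDefinition(n_terminal=(1, 2))
                  for cid in interface_dimer.chains}
        with caplog.at_level(logging.WARNING, logger="saltnet"):
            pairs = classify_pairs(find_ion_pairs(interface_dimer), narrow)
        assert all(set(p.regions) == {"unassigned"} for p in pairs)
        assert any("outside all region intervals" in r.message for r in caplog.records)

    def test_domain_definition_rejects_overlaps(self):
        with pytest.raises(ValueError, match="overlapping"):
            DomainDefinition(large_domain=((1, 100), (50, 150)))

    def test_region_priority_terminal_over_domain(self):
        d = DomainDefinition(large_domain=((1, 100),), small_domain=((101, 200),),
                             n_terminal=(1, 30), c_terminal=(180, 200))
        assert d.region_of(10) == "n_terminal"
        assert d.region_of(50) == "large_domain"
        assert d.region_of(150) == "small_domain"
        assert d.region_of(190) == "c_terminal"
        assert d.region_of(500) == "unassigned"


class TestNetworks:
    def test_shared_residue_forms_three_member_network(self):
        s = Structure(source_id="net-toy")
        s.chains["A"] = [
            make_residue("A", 10, "ASP", {"CA": (0, -3, 0), "OD1": (0, 0, 0),
                                          "OD2": (-1, 0, 0)}),
            make_residue("A", 30, "ASP", {"CA": (6, -3, 0), "OD1": (6, 0, 0),
                                          "OD2": (7, 0, 0)}),
        ]
        s.chains["B"] = [
            make_residue("B", 50, "LYS", {"CA": (3, 5, 0), "NZ": (3, 0, 0)}),
        ]
        pairs = find_ion_pairs(s)
        assert len(pairs) == 2
        networks = build_networks(pairs)
        assert len(networks) == 1
        assert networks[0].size == 3
        assert networks[0].member_set() == {
            ("A", 10, "ASP"), ("A", 30, "ASP"), ("B", 50, "LYS"),
        }
        assert len(networks[0].edges) == 2

    def test_networks_partition_pairs(self):
        for seed in range(5):
            structure, _ = make_dimer_fixture(random_fixture_spec(seed))
            pairs = find_ion_pairs(structure)
            networks = build_networks(pairs)
            assert sum(len(n.edges) for n in networks) == len(pairs)
            seen = [r for n in networks for r in n.members]
            assert len(seen) == len(set(seen))
            in_pairs = {p.res_a for p in pairs} | {p.res_b for p in pairs}
            assert set(seen) == in_pairs

    def test_largest_component_first_and_size2_included(self, planted_dimer):
        _, structure, _ = planted_dimer
        networks = build_networks(find_ion_pairs(structure))
        sizes = [n.size for n in networks]
        assert sizes == sorted(sizes, reverse=True)
        assert all(size == 2 for size in sizes)  # isolated planted pairs

    def test_empty_pairs_give_empty_networks(self):
        assert build_networks([]) == []


class TestActiveSite:
    def test_expected_residues_found(self, planted_dimer):
        _, structure, _ = planted_dimer
        expected = [ResidueId("A", 10, "ARG"), ResidueId("B", 20, "GLU")]
        report = active_site_check(structure, expected)
        assert [flag for _, flag in report] == [True, True]

    def test_renamed_residue_flagged(self, planted_dimer):
        _, structure, _ = planted_dimer
        report = active_site_check(structure, [
            ResidueId("A", 10, "LYS"),   # actually ARG
            ResidueId("A", 999, "ARG"),  # absent
        ])
        assert [flag for _, flag in report] == [False, False]

    def test_empty_expected_list(self, planted_dimer):
        _, structure, _ = planted_dimer
        assert active_site_check(structure, []) == []


def test_pair_table_columns(planted_dimer):
    _, structure, _ = planted_dimer
    pairs = classify_pairs(find_ion_pairs(structure), default_domains(structure))
    df = pairs_to_dataframe(pairs)
    assert list(df.columns) == [
        "chain_a", "res_a", "num_a", "chain_b", "res_b", "num_b",
        "min_distance", "span", "region_a", "region_b",
    ]
    assert (df["min_distance"] <= 4.0).all()


def test_detection_on_biological_assembly(monomer_biomt):
    _, structure, truth = monomer_biomt
    assembly = build_assembly(structure, "biological_assembly")
    pairs = find_ion_pairs(assembly)
    assert len(pairs) == len(truth.expected_ion_pairs)
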