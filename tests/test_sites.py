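import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pocketeval as pe
from pocketeval.errors import InvariantError, UndefinedResultError
from pocketeval.model import Atom, Chain, Residue

fingerprints = st.frozensets(st.integers(min_value=1, max_value=40), min_size=1, max_size=12)


def _chain_on_line(uniprot_nums, spacing=8.0):
    """Single-atom residues spaced far apart on the x axis."""
    residues = [
        Residue(
            auth_seq_id=i + 1,
            name="ALA",
            atoms=[Atom(element="C", coords=np.array([i * spacing, 0.0, 0.0]))],
            uniprot_num=num,
        )
        for i, num in enumerate(uniprot_nums)
    ]
    return Chain(structure_id="X", chain_id="A", residues=residues)


class TestRelativeIntersection:
    @pytest.mark.parametrize(
        "a, b, i_rel",
        [
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1, 2, 3, 4}, {3, 4, 5}, 2 / 3),
        ],
    )
    def test_examples(self, a, b, i_rel):
        got_i, got_d = pe.relative_intersection(frozenset(a), frozenset(b))
        assert got_i == pytest.approx(i_rel)
        assert got_d == pytest.approx(1 - i_rel)

    def test_empty_input_rejected(self):
        with pytest.raises(InvariantError):
            pe.relative_intersection(frozenset(), frozenset({1}))

    @given(a=fingerprints, b=fingerprints)
    @settings(derandomize=True, max_examples=200)
    def test_symmetric_and_bounded(self, a, b):
        i_ab, d_ab = pe.relative_intersection(a, b)
        i_ba, d_ba = pe.relative_intersection(b, a)
        assert i_ab == i_ba and d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0
        assert pe.relative_intersection(a, a) == (1.0, 0.0)


class TestComputeContacts:
    def test_single_contact_within_cutoff(self):
        chain = _chain_on_line([101, 150])
        lig = [Atom(element="C", coords=np.array([3.0, 0.0, 0.0]))]
        assert pe.compute_contacts(chain, lig, cutoff=4.5) == frozenset({101})

    def test_far_ligand_gives_empty_fingerprint(self):
        chain = _chain_on_line([101, 150])
        lig = [Atom(element="C", coords=np.array([0.0, 50.0, 0.0]))]
        assert pe.compute_contacts(chain, lig, cutoff=4.5) == frozenset()

    def test_two_atoms_touch_two_residues_matches_brute_force(self):
        chain = _chain_on_line([101, 150])
        lig = [
            Atom(element="C", coords=np.array([1.0, 0.0, 0.0])),
            Atom(element="C", coords=np.array([7.5, 0.0, 0.0])),
        ]
        got = pe.compute_contacts(chain, lig, cutoff=4.5)
        expected = set()
        for res in chain.residues:
            for a in res.atoms:
                for l in lig:
                    if np.linalg.norm(a.coords - l.coords) <= 4.5:
                        expected.add(res.uniprot_num)
        assert got == frozenset(expected) == frozenset({101, 150})

    def test_unmapped_contacting_residue_is_an_error(self):
        chain = _chain_on_line([None, 150])
        lig = [Atom(element="C", coords=np.array([0.5, 0.0, 0.0]))]
        with pytest.raises(UndefinedResultError):
            pe.compute_contacts(chain, lig, cutoff=4.5)


class TestDeduplicateInterfaces:
    def test_fourteen_identical_collapse_to_one(self):
        fp = frozenset({10, 11, 12})
        groups = pe.deduplicate_interfaces([(f"lig_{i}", fp) for i in range(14)])
        assert len(groups) == 1
        assert groups[0].multiplicity == 14

    def test_thirty_six_as_twelve_triplicates_collapse_to_twelve(self):
        entries = []
        for k in range(12):
            fp = frozenset({100 * k + 1, 100 * k + 2})
            entries.extend((f"lig_{k}_{c}", fp) for c in range(3))
        groups = pe.deduplicate_interfaces(entries)
        assert len(groups) == 12
        assert all(g.multiplicity == 3 for g in groups)

    def test_distinct_fingerprints_stay_separate(self):
        groups = pe.deduplicate_interfaces(
            [("a", frozenset({1})), ("b", frozenset({2})), ("c", frozenset({3}))]
        )
        assert len(groups) == 3
        assert all(g.multiplicity == 1 for g in groups)

    def test_empty_fingerprints_excluded(self):
        groups = pe.deduplicate_interfaces([("a", frozenset()), ("b", frozenset({1}))])
        assert len(groups) == 1


class TestDefineSites:
    def test_identical_fingerprints_one_site(self):
        groups = pe.deduplicate_interfaces(
            [("a", frozenset({1, 2})), ("b", frozenset({1, 2}))]
        )
        sites = pe.define_sites(groups)
        assert len(sites) == 1
        assert sites[0].residues == frozenset({1, 2})

    def test_boundary_merge_at_cut_distance(self):
        # D(F1,F2) = 0.5 exactly: merges at the cut; F3 disjoint stays apart
        groups = pe.deduplicate_interfaces(
            [
                ("a", frozenset({1, 2, 3, 4})),
                ("b", frozenset({3, 4, 5, 6})),
                ("c", frozenset({10, 11, 12, 13})),
            ]
        )
        sites = pe.define_sites(groups, cut=0.5)
        residue_sets = sorted((sorted(s.residues) for s in sites), key=len)
        assert len(sites) == 2
        assert residue_sets == [[10, 11, 12, 13], [1, 2, 3, 4, 5, 6]]

    def test_mutually_disjoint_fingerprints_one_site_each(self):
        groups = pe.deduplicate_interfaces(
            [(f"l{k}", frozenset({10 * k + 1, 10 * k + 2})) for k in range(6)]
        )
        sites = pe.define_sites(groups)
        assert len(sites) == 6

    def test_output_partitions_input_groups(self):
        rng = np.random.default_rng(11)
        entries = [
            (f"l{i}", frozenset(rng.choice(30, size=rng.integers(2, 8), replace=False) + 1))
            for i in range(20)
        ]
        groups = pe.deduplicate_interfaces(entries)
        sites = pe.define_sites(groups)
        members = [m for s in sites for m in s.members]
        assert sorted(members) == sorted(m for g in groups for m in g.members)
        assert sum(s.multiplicity for s in sites) == len(groups)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        entries = [
            (f"l{i}", frozenset(rng.choice(25, size=5, replace=False) + 1))
            for i in range(12)
        ]
        sites_a = pe.define_sites(pe.deduplicate_interfaces(entries))
        sites_b = pe.define_sites(pe.deduplicate_interfaces(entries[::-1]))
        sets_a = sorted(sorted(s.residues) for s in sites_a)
        sets_b = sorted(sorted(s.residues) for s in sites_b)
        assert sets_a == sets_b

    def test_duplicate_fingerprint_never_changes_partition(self):
        entries = [
            ("a", frozenset({1, 2, 3})),
            ("b", frozenset({2, 3, 4})),
            ("c", frozenset({20, 21})),
        ]
        base = pe.define_sites(pe.deduplicate_interfaces(entries))
        dup = pe.define_sites(pe.deduplicate_interfaces(entries + [("d", frozenset({1, 2, 3}))]))
        assert sorted(sorted(s.residues) for s in base) == sorted(
            sorted(s.residues) for s in dup
        )

    @given(
        fps=st.lists(fingerprints, min_size=1, max_size=8, unique=True).filter(
            lambda fps: all(
                not (a & b) for i, a in enumerate(fps) for b in fps[i + 1:]
            )
        )
    )
    @settings(derandomize=True, max_examples=60)
    def test_all_pairwise_disjoint_means_one_site_per_group(self, fps):
        groups = pe.deduplicate_interfaces([(f"l{i}", fp) for i, fp in enumerate(fps)])
        assert len(pe.define_sites(groups)) == len(groups)


class TestSiteCentroid:
    def test_single_atom_site(self):
        chain = _chain_on_line([5])
        site = pe.BindingSite(site_id="s", residues={5}, members=("l",))
        np.testing.assert_allclose(pe.site_centroid(site, chain), [0.0, 0.0, 0.0])

    def test_symmetry_two_residues(self):
        residues = [
            Residue(auth_seq_id=1, name="ALA", uniprot_num=1,
                    atoms=[Atom(element="C", coords=np.zeros(3))]),
            Residue(auth_seq_id=2, name="ALA", uniprot_num=2,
                    atoms=[Atom(element="C", coords=np.array([2.0, 0.0, 0.0]))]),
        ]
        chain = Chain(structure_id="X", chain_id="A", residues=residues)
        site = pe.BindingSite(site_id="s", residues={1, 2}, members=("l",))
        np.testing.assert_allclose(pe.site_centroid(site, chain), [1.0, 0.0, 0.0])

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(5)
        residues = []
        for i in range(3):
            atoms = [
                Atom(element="C", coords=rng.normal(size=3) * 5) for _ in range(4)
            ]
            residues.append(
                Residue(auth_seq_id=i + 1, name="ALA", uniprot_num=i + 1, atoms=atoms)
            )
        chain = Chain(structure_id="X", chain_id="A", residues=residues)
        site = pe.BindingSite(site_id="s", residues={1, 2, 3}, members=("l",))
        expected = np.mean(
            [a.coords for r in residues for a in r.atoms], axis=0
        )
        np.testing.assert_allclose(pe.site_centroid(site, chain), expected)

    def test_absent_residues_undefined(self):
        chain = _chain_on_line([1])
        site = pe.BindingSite(site_id="s", residues={99}, members=("l",))
        with pytest.raises(UndefinedResultError):
            pe.site_centroid(site, chain)
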