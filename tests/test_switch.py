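from fractions import Fraction

import numpy as np
import pytest

from lipidtraffic import (
    Scope,
    align_binary_lists,
    binarize,
    classification_table,
    classify_switch,
    parse_lipid_name,
    presence_fraction,
)
from conftest import brute_force_classify, make_dataset, random_small_instance


class TestPresenceFraction:
    def test_examples(self):
        assert presence_fraction([1.2, 0, 3.4, 5.0]) == Fraction(3, 4)
        assert presence_fraction([0, 0, 0]) == 0

    def test_six_of_eight_is_present_at_066(self):
        frac = presence_fraction([1] * 6 + [0] * 2)
        assert frac == Fraction(3, 4)
        assert frac >= Fraction("0.66")

    def test_five_of_eight_is_absent_at_066(self):
        assert presence_fraction([1] * 5 + [0] * 3) < Fraction("0.66")

    def test_exact_at_threshold_is_present(self):
        # a closed bound: exactly 66/100 counts as present
        assert presence_fraction([1] * 66 + [0] * 34) >= Fraction("0.66")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            presence_fraction([])


class TestBinarize:
    def test_toy_profile(self, toy_dataset):
        profile = binarize(toy_dataset)
        present = profile.present
        assert present.loc[("lean", "serum"), "TG(52:3)"]
        assert present.loc[("lean", "serum"), "PC(34:1)"] == False  # noqa: E712
        assert present.loc[("obese", "liver"), "SM(39:1)"] == False  # noqa: E712
        assert (profile.b_fraction.to_numpy() <= 1).all()

    def test_threshold_zero_degenerate(self, toy_dataset):
        # present <=> B >= threshold, and every B >= 0: in particular any
        # variable with a nonzero sample is present
        present = binarize(toy_dataset, 0).present
        assert present.to_numpy().all()

    def test_empty_cell_named_in_error(self, toy_dataset):
        trimmed = toy_dataset.samples.drop(
            toy_dataset.samples.index[
                (toy_dataset.samples["group"] == "obese")
                & (toy_dataset.samples["compartment"] == "liver")
            ]
        )
        ds = make_dataset(
            [
                (sid, trimmed.loc[sid, "compartment"], trimmed.loc[sid, "group"],
                 toy_dataset.abundance.loc[sid].tolist())
                for sid in trimmed.index
            ],
            toy_dataset.variable_names,
        )
        with pytest.raises(ValueError, match="obese.*liver"):
            binarize(ds)


class TestClassify:
    def test_toy_categories(self, toy_dataset, two_compartment_network):
        classes = classify_switch(binarize(toy_dataset), two_compartment_network)
        lean, obese = classes["lean"], classes["obese"]
        # ubiquitous in both groups
        assert "TG(52:3)" in lean.a_list and "TG(52:3)" in obese.a_list
        # unique to liver in both groups
        assert "PC(34:1)" in lean.u_lists["liver"]
        assert "PC(34:1)" not in lean.u_lists["serum"]
        # group-specific ubiquity
        assert "SM(39:1)" in lean.a_list
        assert "SM(39:1)" in obese.not_detected
        # A-list members sit on every edge's B-list
        edge = ("liver", "serum")
        assert lean.a_list <= lean.b_lists[edge]

    def test_compartment_mismatch_rejected(self, toy_dataset, star_network):
        with pytest.raises(ValueError, match="lacks network compartments"):
            classify_switch(binarize(toy_dataset), star_network)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_instances(self, seed):
        """classify_switch agrees with a brute-force recomputation from the
        raw abundance matrix."""
        rng = np.random.default_rng(1000 + seed)
        dataset, network = random_small_instance(rng)
        classes = classify_switch(binarize(dataset), network)
        oracle = brute_force_classify(dataset.abundance, dataset.samples, network)
        for g, cls in classes.items():
            assert cls.a_list == oracle[g]["A"]
            for c in network.compartments:
                assert cls.u_lists[c] == oracle[g]["U"][c]
            for e, members in cls.b_lists.items():
                assert members == oracle[g]["B"][e]

    @pytest.mark.parametrize("seed", range(5))
    def test_category_partition_and_invariants(self, seed):
        rng = np.random.default_rng(2000 + seed)
        dataset, network = random_small_instance(rng)
        classes = classify_switch(binarize(dataset), network)
        n_comp = len(network.compartments)
        for cls in classes.values():
            all_u = set().union(*cls.u_lists.values())
            multi = {
                v for v, r in cls.records.items()
                if 1 < len(r.present_compartments) < n_comp
            }
            # U + A + multi + not-detected partitions the variables
            parts = [all_u, cls.a_list, multi, cls.not_detected]
            assert set.union(*parts) == set(dataset.variable_names)
            assert sum(len(p) for p in parts) == len(dataset.variable_names)
            for members in cls.b_lists.values():
                assert cls.a_list <= members
                assert not (all_u & members)

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        """Raising the threshold never adds presence calls."""
        rng = np.random.default_rng(3000 + seed)
        dataset, network = random_small_instance(rng)
        lo = binarize(dataset, "0.5").present
        hi = binarize(dataset, "0.8").present
        assert (hi.to_numpy() <= lo.to_numpy()).all()


class TestAlign:
    def _classes(self, toy_dataset, net):
        return classify_switch(binarize(toy_dataset), net)

    def test_union_and_vectors(self, toy_dataset, two_compartment_network):
        classes = self._classes(toy_dataset, two_compartment_network)
        aligned = align_binary_lists(
            classes["lean"], classes["obese"], Scope("A"), toy_dataset.variables
        )
        # union {TG(52:3), SM(39:1)} in canonical (class-sorted) order
        assert aligned.names == ["SM(39:1)", "TG(52:3)"]
        assert aligned.vector_g1.tolist() == [1, 1]
        assert aligned.vector_g2.tolist() == [0, 1]

    def test_identical_lists_identical_vectors(self, toy_dataset, two_compartment_network):
        classes = self._classes(toy_dataset, two_compartment_network)
        aligned = align_binary_lists(
            classes["lean"], classes["obese"],
            Scope("U", compartment="liver"), toy_dataset.variables,
        )
        assert aligned.vector_g1.tolist() == aligned.vector_g2.tolist() == [1]

    def test_empty_union_is_an_error(self, toy_dataset, two_compartment_network):
        classes = self._classes(toy_dataset, two_compartment_network)
        with pytest.raises(ValueError, match="nothing to compare"):
            align_binary_lists(
                classes["lean"], classes["obese"],
                Scope("U", compartment="serum"), toy_dataset.variables,
            )

    def test_lipid_class_filter(self, toy_dataset, two_compartment_network):
        classes = self._classes(toy_dataset, two_compartment_network)
        aligned = align_binary_lists(
            classes["lean"], classes["obese"],
            Scope("A", lipid_class="SM"), toy_dataset.variables,
        )
        assert aligned.names == ["SM(39:1)"]
        assert aligned.vector_g2.tolist() == [0]


def test_classification_table_long_format(toy_dataset, two_compartment_network):
    classes = classify_switch(binarize(toy_dataset), two_compartment_network)
    table = classification_table(classes)
    assert len(table) == 2 * 3  # groups x variables
    row = table[(table.group == "obese") & (table.variable == "SM(39:1)")].iloc[0]
    assert row.category == "absent" and row.n_compartments == 0
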