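"""Construction grammar: enumeration, naming, composition, defects, SMILES."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamcas.composition import ElementalComposition
from pamcas.grammar import (
    AMIDE_COUPLING_DELTA,
    BuildingBlock,
    DefectVariant,
    DendrimerSpec,
    NameParseError,
    Registry,
    SmilesUnsupportedError,
    activated_ester_composition,
    average_mass,
    defect_ladder,
    elemental_composition,
    enumerate_sequences,
    parse_name,
    peripheral_group_count,
    pg_class_histogram,
    smiles,
    spec_name,
)


def grown_composition_oracle(spec):
    """Brute-force atom bookkeeping of the stepwise synthesis.

    Simulates the actual reaction sequence, one reagent at a time:
    TEC-cap every end group (add the full cap), then amide-couple the
    next layer block at every site (add block, remove H2O + HCl).
    Independent of the recursive site-contribution formula it checks.
    """
    comp = spec.core.composition
    n_sites = spec.core.multiplicity
    for block in spec.layers:
        comp = comp + n_sites * spec.cap.composition  # TEC on every allyl
        comp = comp + n_sites * block.composition  # couple the next layer
        comp = comp - n_sites * AMIDE_COUPLING_DELTA
        n_sites *= block.multiplicity
    if spec.terminal_form == "ammonium":
        comp = comp + n_sites * spec.cap.composition
    return comp


class TestEnumeration:
    def test_two_blocks_generation_three_gives_eight(self, registry):
        specs = enumerate_sequences(
            3, registry.branch_blocks, core=registry.core, cap=registry.cap
        )
        assert len(specs) == 8
        assert len({s.name for s in specs}) == 8

    def test_single_block_single_layer(self, registry, ab3):
        specs = enumerate_sequences(
            1, [ab3], core=registry.core, cap=registry.cap
        )
        assert len(specs) == 1
        assert specs[0].layers == (ab3,)

    def test_fourteen_sequences_across_three_generations(self, registry):
        total = sum(
            len(
                enumerate_sequences(
                    n, registry.branch_blocks, core=registry.core,
                    cap=registry.cap,
                )
            )
            for n in (1, 2, 3)
        )
        assert total == 14

    def test_order_is_lexicographic_by_layer_names(self, registry):
        specs = enumerate_sequences(
            2, registry.branch_blocks, core=registry.core, cap=registry.cap
        )
        names = [tuple(b.name for b in s.layers) for s in specs]
        assert names == sorted(names)

    def test_generation_zero_rejected(self, registry):
        with pytest.raises(ValueError, match="generation"):
            enumerate_sequences(
                0, registry.branch_blocks, core=registry.core, cap=registry.cap
            )

    def test_empty_block_set_rejected(self, registry):
        with pytest.raises(ValueError, match="non-empty"):
            enumerate_sequences(1, [], core=registry.core, cap=registry.cap)


class TestPeripheralGroups:
    @pytest.mark.parametrize(
        "tokens, expected",
        [
            (("6", "6", "6"), 864),
            (("3", "3", "3"), 108),
            (("6", "6"), 144),
            (("3", "3"), 36),
            (("3", "6"), 72),
            ((), 4),
        ],
    )
    def test_counts(self, make_spec, tokens, expected):
        assert peripheral_group_count(make_spec(*tokens)) == expected

    def test_multiplicative_in_appended_layer(self, registry, make_spec, ab6):
        spec = make_spec("3", "6")
        extended = DendrimerSpec(
            core=spec.core,
            layers=spec.layers + (ab6,),
            terminal_form=spec.terminal_form,
            cap=spec.cap,
        )
        assert peripheral_group_count(extended) == (
            peripheral_group_count(spec) * ab6.multiplicity
        )

    def test_pamam_style_branching(self, registry):
        """A tetravalent core with two 2-fold layers carries 16 end groups."""
        b2 = BuildingBlock(
            name="B2",
            role="branch",
            composition=ElementalComposition.from_formula("C4H6O2"),
            multiplicity=2,
            token="2",
        )
        spec = DendrimerSpec(
            core=registry.core,
            layers=(b2, b2),
            terminal_form="allyl",
            cap=registry.cap,
        )
        assert peripheral_group_count(spec) == 16


class TestPgClassHistogram:
    def test_generation_three_follows_pascal(self, registry):
        hist = pg_class_histogram(
            3, registry.branch_blocks, core=registry.core
        )
        assert hist == {108: 1, 216: 3, 432: 3, 864: 1}

    def test_generation_one(self, registry):
        hist = pg_class_histogram(
            1, registry.branch_blocks, core=registry.core
        )
        assert hist == {12: 1, 24: 1}

    def test_single_block_collapses_to_one_class(self, registry, ab3):
        hist = pg_class_histogram(3, [ab3], core=registry.core)
        assert hist == {108: 1}

    @pytest.mark.parametrize("generation", [1, 2, 3, 4])
    def test_values_sum_to_k_power_n_with_binomial_classes(
        self, registry, generation
    ):
        hist = pg_class_histogram(
            generation, registry.branch_blocks, core=registry.core
        )
        assert sum(hist.values()) == 2**generation
        from math import comb

        assert sorted(hist.values()) == sorted(
            comb(generation, i) for i in range(generation + 1)
        )


class TestComposition:
    def test_module_masses_match_printed_values(self, ab3, ab6):
        assert round(ab3.average_mass) == 330
        assert round(ab6.average_mass) == 539

    def test_g2_3_6_ammonium_mass(self, make_spec):
        assert average_mass(make_spec("3", "6")) == pytest.approx(17107, abs=1)

    def test_generation_three_mass_bounds(self, make_spec):
        assert average_mass(make_spec("3", "3", "3")) / 1000 >= 32
        assert average_mass(make_spec("6", "6", "6")) / 1000 >= 200

    def test_activated_ester_mass_ratio(self, make_spec, ab3):
        g13a = make_spec("3", form="allyl")
        ratio = average_mass(g13a) / activated_ester_composition(ab3).average_mass
        assert round(ratio, 1) == 3.9

    @pytest.mark.parametrize(
        "tokens, form",
        [
            ((), "allyl"),
            ((), "ammonium"),
            (("3",), "allyl"),
            (("6",), "ammonium"),
            (("3", "6"), "ammonium"),
            (("6", "3"), "allyl"),
            (("6", "6"), "ammonium"),
            (("3", "6", "3"), "ammonium"),
        ],
    )
    def test_matches_stepwise_growth_oracle(self, make_spec, tokens, form):
        spec = make_spec(*tokens, form=form)
        assert elemental_composition(spec) == grown_composition_oracle(spec)

    def test_ammonium_minus_allyl_is_npg_caps(self, registry, make_spec):
        """TEC is atom-economic: the N/A mass gap is exactly N_PG caps."""
        cap_mass = registry.cap.average_mass
        for tokens in itertools.chain.from_iterable(
            itertools.product("36", repeat=n) for n in (0, 1, 2, 3)
        ):
            n_form = make_spec(*tokens, form="ammonium")
            a_form = make_spec(*tokens, form="allyl")
            gap = average_mass(n_form) - average_mass(a_form)
            expected = peripheral_group_count(n_form) * cap_mass
            assert gap == pytest.approx(expected, rel=1e-12)

    def test_layers_without_cap_rejected(self, registry, ab3):
        spec = DendrimerSpec(
            core=registry.core, layers=(ab3,), terminal_form="allyl", cap=None
        )
        with pytest.raises(ValueError, match="cap"):
            elemental_composition(spec)


class TestNaming:
    @pytest.mark.parametrize(
        "tokens, form, expected",
        [
            (("6", "3"), "ammonium", "G2-6-3-N"),
            (("3",), "allyl", "G1-3-A"),
            ((), "ammonium", "G0-N"),
            (("6", "6", "6"), "allyl", "G3-6-6-6-A"),
        ],
    )
    def test_name(self, make_spec, tokens, form, expected):
        assert spec_name(make_spec(*tokens, form=form)) == expected

    def test_round_trip_on_all_fourteen_specs(self, registry):
        for n in (1, 2, 3):
            for spec in enumerate_sequences(
                n, registry.branch_blocks, core=registry.core, cap=registry.cap
            ):
                assert parse_name(spec.name, registry) == spec

    @given(
        st.lists(st.sampled_from(["3", "6"]), max_size=4),
        st.sampled_from(["allyl", "ammonium"]),
    )
    @settings(max_examples=40, derandomize=True)
    def test_round_trip_property(self, tokens, form):
        registry = Registry.default()
        spec = DendrimerSpec(
            core=registry.core,
            layers=tuple(registry.by_token(t) for t in tokens),
            terminal_form=form,
            cap=registry.cap,
        )
        assert parse_name(spec_name(spec), registry) == spec

    @pytest.mark.parametrize(
        "label, position",
        [
            ("X2-3-6-N", 0),
            ("G2-3-6", 5),
            ("G2-3-N", 3),
            ("G1-X-N", 3),
            ("G2-3-6-Q", 7),
        ],
    )
    def test_parse_errors_carry_position(self, registry, label, position):
        with pytest.raises(NameParseError) as err:
            parse_name(label, registry)
        assert err.value.position == position


class TestDefects:
    def test_zero_defect_variant_equals_perfect(self, make_spec):
        spec = make_spec("6")
        variant = DefectVariant(base=spec)
        assert variant.composition == elemental_composition(spec)

    def test_ladder_is_arithmetic_in_cap_mass(self, registry, make_spec):
        ladder = defect_ladder(make_spec("6"), 5)
        assert len(ladder) == 6
        masses = [m for _, m in ladder]
        assert masses == sorted(masses, reverse=True)
        spacings = [a - b for a, b in zip(masses, masses[1:])]
        for spacing in spacings:
            assert spacing == pytest.approx(
                registry.cap.average_mass, abs=1e-9
            )
        # the cysteamine-hydrochloride rung spacing is ~113.6 g/mol
        assert spacings[0] == pytest.approx(113.603, abs=0.01)

    def test_ladder_beyond_site_count_rejected(self, make_spec):
        with pytest.raises(ValueError, match="exceeds"):
            defect_ladder(make_spec("3"), 13)  # G1-3-N has 12 sites

    def test_missing_branch_keeps_capped_site(self, registry, make_spec):
        """A missing outer AB6 branch removes block+6 caps but keeps the
        site's own ammonium chloride terminus."""
        spec = make_spec("3", "6")
        variant = DefectVariant(base=spec, missing_branches={1: 1})
        block = registry["AB6"]
        expected_loss = (
            block.average_mass
            - AMIDE_COUPLING_DELTA.average_mass
            + block.multiplicity * registry.cap.average_mass
        )
        loss = average_mass(spec) - variant.composition.average_mass
        assert loss == pytest.approx(expected_loss, rel=1e-12)

    def test_missing_branch_in_allyl_form_gains_chloride(self, make_spec):
        """An unreacted site in an allyl-form species retains its HCl."""
        spec = make_spec("3", form="allyl")
        variant = DefectVariant(base=spec, missing_branches={0: 1})
        assert variant.composition["Cl"] == 1

    def test_more_missing_than_sites_rejected(self, make_spec):
        with pytest.raises(ValueError, match="attachment sites"):
            DefectVariant(base=make_spec("3", "6"), missing_branches={0: 5})

    def test_cap_defects_require_ammonium_form(self, make_spec):
        with pytest.raises(ValueError, match="ammonium"):
            DefectVariant(base=make_spec("3", form="allyl"), missing_caps=1)


class TestSmiles:
    @staticmethod
    def atom_counts(text):
        from collections import Counter

        pytest.importorskip("rdkit")
        from rdkit import Chem

        mol = Chem.MolFromSmiles(text)
        assert mol is not None, "SMILES failed to parse"
        mol = Chem.AddHs(mol)
        return Counter(atom.GetSymbol() for atom in mol.GetAtoms())

    def test_core_allyl_form_is_tetraallylsilane(self, make_spec):
        counts = self.atom_counts(smiles(make_spec(form="allyl")))
        assert counts == {"C": 12, "H": 20, "Si": 1}

    @pytest.mark.parametrize(
        "tokens, form",
        [((), "ammonium"), (("3",), "allyl"), (("3",), "ammonium"),
         (("6", "3"), "ammonium")],
    )
    def test_atom_counts_match_composition(self, make_spec, tokens, form):
        spec = make_spec(*tokens, form=form)
        assert dict(self.atom_counts(smiles(spec))) == dict(
            elemental_composition(spec)
        )

    def test_unannotated_block_raises(self, registry):
        bare = BuildingBlock(
            name="bare",
            role="branch",
            composition=ElementalComposition.from_formula("C4H6O2"),
            multiplicity=2,
            coupling_delta=AMIDE_COUPLING_DELTA,
        )
        spec = DendrimerSpec(
            core=registry.core,
            layers=(bare,),
            terminal_form="ammonium",
            cap=registry.cap,
        )
        with pytest.raises(SmilesUnsupportedError, match="bare"):
            smiles(spec)


class TestRegistry:
    def test_default_registry_blocks(self, registry):
        assert {b.name for b in registry} == {"core", "AB3", "AB6", "CA-HCl"}
        assert registry.core.multiplicity == 4
        assert registry.cap.multiplicity == 1

    def test_unknown_block_raises_registry_error(self, registry):
        from pamcas.grammar import RegistryError

        with pytest.raises(RegistryError, match="AB9"):
            registry["AB9"]

    def test_yaml_round_trip(self, registry, tmp_path):
        from importlib import resources

        source = resources.files("pamcas").joinpath(
            "data/default_registry.yaml"
        )
        target = tmp_path / "registry.yaml"
        target.write_text(source.read_text(encoding="utf-8"))
        loaded = Registry.from_yaml(target)
        assert {b.name for b in loaded} == {b.name for b in registry}
        assert loaded["AB6"].composition == registry["AB6"].composition
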