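"""Modular dendrimer construction grammar.

The dendrimers modelled here grow from a tetravalent silicon core by
alternating two reactions:

* **thiol-ene click (TEC)** — anti-Markovnikov addition of a cysteamine
  hydrochloride cap across every terminal allyl group.  The reaction is
  atom-economic: the full cap composition is added, nothing is lost.
  It converts an allyl-terminated ("-A") species into an ammonium-
  terminated ("-N") one.
* **amide coupling** — condensation of a branch module's focal carboxylic
  acid with every peripheral ammonium group, releasing H2O (amide bond)
  plus HCl (the amine is carried as its hydrochloride salt).

A :class:`DendrimerSpec` is the central object: a core, an ordered layer
sequence (innermost first) of branch blocks, and a terminal form.  With
two interchangeable branch blocks of multiplicity 3 (AB3) and 6 (AB6)
this grammar generates ``2**n`` distinct structures per generation *n*,
whose end-group-count classes follow Pascal's triangle, and peripheral
group counts up to 864 in generation 3.

All compositions, masses, names, defect ladders and SMILES strings are
derived from the block registry; the shipped defaults reproduce the
printed molecular weights of the synthesised compounds (modules 330 and
539 g/mol, G2-3-6-N at 17,107 g/mol, generation-3 ammonium species from
32.7 to 201.2 kDa).
"""

from __future__ import annotations

import itertools
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .composition import (
    EMPTY,
    HYDROGEN_CHLORIDE,
    WATER,
    ElementalComposition,
)

AMIDE_COUPLING_DELTA = WATER + HYDROGEN_CHLORIDE

_ROLES = ("core", "branch", "cap")
_TERMINAL_FORMS = ("allyl", "ammonium")
_FORM_SUFFIX = {"allyl": "A", "ammonium": "N"}
_SUFFIX_FORM = {v: k for k, v in _FORM_SUFFIX.items()}


class RegistryError(KeyError):
    """An operation referenced a block the registry does not provide."""


class NameParseError(ValueError):
    """A dendrimer name failed to parse; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class BuildingBlock:
    """A named monomer, core or cap with its coupling bookkeeping.

    Parameters
    ----------
    name
        Registry label, e.g. ``"AB3"``.
    role
        One of ``core``, ``branch``, ``cap``.
    composition
        Elemental composition of the free block (acid form for branches,
        hydrochloride salt for the cap).
    multiplicity
        Reactive end groups produced per attachment: 4 for the core,
        3/6 for the AB3/AB6 wedges, 1 for the cap.
    coupling_delta
        Composition removed when the block is attached (H2O + HCl per
        amide coupling onto an ammonium chloride end group; empty for
        the atom-economic TEC cap).
    token
        Single token used for this block in compound names ("3", "6").
    smiles_fragment
        Attachment-annotated substructure with ``{a}`` placeholders, one
        per multiplicity (core and branch blocks).
    terminal_smiles
        Arm emitted for an unreacted allyl terminus.
    smiles_arm, smiles_head, smiles_counterion
        Cap-specific: thioether tether, charged head group, counterion.
    """

    name: str
    role: str
    composition: ElementalComposition
    multiplicity: int
    coupling_delta: ElementalComposition = EMPTY
    token: str | None = None
    smiles_fragment: str | None = None
    terminal_smiles: str = "CC=C"
    smiles_arm: str | None = None
    smiles_head: str | None = None
    smiles_counterion: str | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.multiplicity < 1:
            raise ValueError(
                f"multiplicity must be >= 1, got {self.multiplicity}"
            )

    @property
    def average_mass(self) -> float:
        return self.composition.average_mass

    @property
    def monoisotopic_mass(self) -> float:
        return self.composition.monoisotopic_mass


class Registry:
    """Lookup table of building blocks, keyed by name and by name token."""

    def __init__(self, blocks: Iterable[BuildingBlock]):
        self._by_name: dict[str, BuildingBlock] = {}
        self._by_token: dict[str, BuildingBlock] = {}
        cores = []
        caps = []
        for block in blocks:
            if block.name in self._by_name:
                raise ValueError(f"duplicate block name {block.name!r}")
            self._by_name[block.name] = block
            if block.token is not None:
                if block.token in self._by_token:
                    raise ValueError(f"duplicate block token {block.token!r}")
                self._by_token[block.token] = block
            if block.role == "core":
                cores.append(block)
            elif block.role == "cap":
                caps.append(block)
        if len(cores) != 1:
            raise ValueError(f"registry needs exactly one core, got {len(cores)}")
        if len(caps) != 1:
            raise ValueError(f"registry needs exactly one cap, got {len(caps)}")
        self._core = cores[0]
        self._cap = caps[0]

    @property
    def core(self) -> BuildingBlock:
        return self._core

    @property
    def cap(self) -> BuildingBlock:
        return self._cap

    @property
    def branch_blocks(self) -> tuple[BuildingBlock, ...]:
        return tuple(
            b for b in self._by_name.values() if b.role == "branch"
        )

    def __getitem__(self, name: str) -> BuildingBlock:
        try:
            return self._by_name[name]
        except KeyError:
            raise RegistryError(f"no block named {name!r} in registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def by_token(self, token: str) -> BuildingBlock:
        try:
            return self._by_token[token]
        except KeyError:
            raise RegistryError(f"no block with name token {token!r}") from None

    # -- construction ----------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "Registry":
        blocks = []
        for entry in data["blocks"]:
            entry = dict(entry)
            formula = entry.pop("formula")
            delta = entry.pop("coupling_delta", None)
            blocks.append(
                BuildingBlock(
                    composition=ElementalComposition.from_formula(formula),
                    coupling_delta=(
                        ElementalComposition.from_formula(delta)
                        if delta
                        else EMPTY
                    ),
                    **{k: v for k, v in entry.items() if v is not None or k in (
                        "token", "smiles_fragment", "smiles_arm",
                        "smiles_head", "smiles_counterion",
                    )},
                )
            )
        return cls(blocks)

    @classmethod
    def from_yaml(cls, path) -> "Registry":
        with open(path, "r", encoding="utf-8") as handle:
            return cls.from_dict(yaml.safe_load(handle))

    @classmethod
    def default(cls) -> "Registry":
        """The shipped registry (core, AB3, AB6, cysteamine-HCl cap)."""
        source = resources.files("pamcas").joinpath("data/default_registry.yaml")
        return cls.from_dict(yaml.safe_load(source.read_text(encoding="utf-8")))


@dataclass(frozen=True)
class DendrimerSpec:
    """Core + ordered branch layers (innermost first) + terminal form."""

    core: BuildingBlock
    layers: tuple[BuildingBlock, ...]
    terminal_form: str = "ammonium"
    cap: BuildingBlock | None = None

    def __post_init__(self) -> None:
        if self.core.role != "core":
            raise ValueError(f"core block has role {self.core.role!r}")
        object.__setattr__(self, "layers", tuple(self.layers))
        for block in self.layers:
            if block.role != "branch":
                raise ValueError(
                    f"layer block {block.name!r} has role {block.role!r}"
                )
        if self.terminal_form not in _TERMINAL_FORMS:
            raise ValueError(
                f"terminal_form must be one of {_TERMINAL_FORMS}, "
                f"got {self.terminal_form!r}"
            )
        if self.terminal_form == "ammonium":
            if self.cap is None:
                raise ValueError("ammonium form requires a cap block")
            if self.cap.role != "cap":
                raise ValueError(f"cap block has role {self.cap.role!r}")

    @property
    def generation(self) -> int:
        return len(self.layers)

    @property
    def name(self) -> str:
        return spec_name(self)


# ---------------------------------------------------------------------------
# naming


def spec_name(spec: DendrimerSpec) -> str:
    """Compound label ``G<generation>-<layer tokens, inner to outer>-<A|N>``."""
    tokens = [f"G{spec.generation}"]
    for block in spec.layers:
        if block.token is None:
            raise ValueError(
                f"layer block {block.name!r} has no name token; cannot name spec"
            )
        tokens.append(block.token)
    tokens.append(_FORM_SUFFIX[spec.terminal_form])
    return "-".join(tokens)


def parse_name(label: str, registry: Registry) -> DendrimerSpec:
    """Parse a compound label back into a :class:`DendrimerSpec`.

    Inverse of :func:`spec_name` on every valid spec.  Raises
    :class:`NameParseError` with the offending character position on
    malformed input.
    """
    parts = label.split("-")
    head = parts[0]
    if not head.startswith("G") or not head[1:].isdigit():
        raise NameParseError(
            f"expected generation field 'G<integer>', got {head!r}", 0
        )
    generation = int(head[1:])
    if len(parts) < 2:
        raise NameParseError("missing terminal-form suffix 'A' or 'N'", len(label))
    suffix = parts[-1]
    suffix_pos = len(label) - len(suffix)
    if suffix not in _SUFFIX_FORM:
        raise NameParseError(
            f"terminal-form suffix must be 'A' or 'N', got {suffix!r}", suffix_pos
        )
    layer_tokens = parts[1:-1]
    if len(layer_tokens) != generation:
        raise NameParseError(
            f"generation {generation} requires {generation} layer tokens, "
            f"got {len(layer_tokens)}",
            len(head) + 1,
        )
    layers = []
    pos = len(head) + 1
    for token in layer_tokens:
        try:
            layers.append(registry.by_token(token))
        except RegistryError:
            raise NameParseError(f"unknown layer token {token!r}", pos) from None
        pos += len(token) + 1
    form = _SUFFIX_FORM[suffix]
    # the cap travels with every spec: allyl-form species of generation >= 1
    # still contain TEC caps at the inner (amide-coupled) sites
    return DendrimerSpec(
        core=registry.core,
        layers=tuple(layers),
        terminal_form=form,
        cap=registry.cap,
    )


# ---------------------------------------------------------------------------
# enumeration and counting


def enumerate_sequences(
    generation: int,
    branch_blocks: Iterable[BuildingBlock],
    *,
    core: BuildingBlock,
    cap: BuildingBlock | None = None,
    terminal_form: str = "ammonium",
) -> list[DendrimerSpec]:
    """All ``k**n`` ordered layer sequences of *n* layers over *k* blocks.

    Order is deterministic: lexicographic by the tuple of layer names.
    """
    if generation < 1:
        raise ValueError(f"generation must be >= 1, got {generation}")
    blocks = sorted(set(branch_blocks), key=lambda b: b.name)
    if not blocks:
        raise ValueError("branch_blocks must be non-empty")
    return [
        DendrimerSpec(core=core, layers=layers, terminal_form=terminal_form,
                      cap=cap)
        for layers in itertools.product(blocks, repeat=generation)
    ]


def peripheral_group_count(spec: DendrimerSpec) -> int:
    """Number of peripheral end groups: core valency x product of layer
    multiplicities (864 for G3-6-6-6, 108 for G3-3-3-3, 4 for the bare core)."""
    count = spec.core.multiplicity
    for block in spec.layers:
        count *= block.multiplicity
    return count


def pg_class_histogram(
    generation: int,
    branch_blocks: Iterable[BuildingBlock],
    *,
    core: BuildingBlock,
) -> dict[int, int]:
    """Histogram of peripheral-group counts over all layer sequences.

    For two blocks the class multiplicities are the binomial coefficients
    of Pascal's triangle (1:3:3:1 in generation 3).
    """
    specs = enumerate_sequences(
        generation, branch_blocks, core=core, terminal_form="allyl"
    )
    return dict(sorted(Counter(peripheral_group_count(s) for s in specs).items()))


# ---------------------------------------------------------------------------
# composition and mass


def _terminal_contribution(spec: DendrimerSpec) -> ElementalComposition:
    """Composition added per terminal site beyond the last branch layer."""
    if spec.terminal_form == "ammonium":
        assert spec.cap is not None
        return spec.cap.composition
    return EMPTY


def _site_contribution(
    spec: DendrimerSpec, layer_index: int
) -> ElementalComposition:
    """Composition carried by one attachment site entering ``layer_index``.

    Every inner site is TEC-capped before its amide coupling, so a site
    at layer *i* contributes cap + block - coupling_delta (the delta,
    H2O + HCl, is lost from the capped-site/block pair, which is why it
    must be subtracted after the cap is added) plus ``multiplicity``
    child sites.  A site beyond the last layer carries the terminal
    contribution: a cap for the ammonium form, nothing for the allyl
    form (the allyl groups belong to the parent block).
    """
    if layer_index == len(spec.layers):
        return _terminal_contribution(spec)
    block = spec.layers[layer_index]
    assert spec.cap is not None
    contribution = (
        spec.cap.composition + block.composition - block.coupling_delta
    )
    return contribution + block.multiplicity * _site_contribution(
        spec, layer_index + 1
    )


def elemental_composition(spec: DendrimerSpec) -> ElementalComposition:
    """Full elemental composition of the perfect structure.

    The core contributes its precursor composition; every inner attachment
    site carries a TEC cap (atom-economic addition) consumed by the next
    amide coupling (releasing H2O + HCl); terminal sites carry either a
    bare allyl group (already part of the parent block) or a cap.
    """
    if spec.layers and spec.cap is None:
        raise ValueError(
            "specs with layers need a cap block (inner couplings consume "
            "TEC-capped sites); construct the spec with cap=registry.cap"
        )
    return spec.core.composition + spec.core.multiplicity * _site_contribution(
        spec, 0
    )


def average_mass(spec: DendrimerSpec) -> float:
    return elemental_composition(spec).average_mass


def monoisotopic_mass(spec: DendrimerSpec) -> float:
    return elemental_composition(spec).monoisotopic_mass


def activated_ester_composition(block: BuildingBlock) -> ElementalComposition:
    """Benzotriazol-1-yl ester of a branch block's focal acid (BtO-AB_x).

    The acid's hydroxyl proton is replaced by a benzotriazol-1-yl group
    (C6H4N3): the stable activated species recovered from coupling
    filtrates of the para-alkoxy module.
    """
    return (
        block.composition
        - ElementalComposition.from_formula("H")
        + ElementalComposition.from_formula("C6H4N3")
    )


# ---------------------------------------------------------------------------
# defect variants


@dataclass(frozen=True)
class DefectVariant:
    """A structure missing end-group caps and/or whole branch subtrees."""

    base: DendrimerSpec
    missing_caps: int = 0
    missing_branches: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.missing_caps < 0:
            raise ValueError("missing_caps must be >= 0")
        if self.missing_caps and self.base.terminal_form != "ammonium":
            raise ValueError(
                "cap defects only exist for ammonium-form species"
            )
        object.__setattr__(
            self, "missing_branches", dict(self.missing_branches)
        )
        sites = self.base.core.multiplicity
        for index, block in enumerate(self.base.layers):
            missing = self.missing_branches.get(index, 0)
            if missing < 0:
                raise ValueError(f"missing count at layer {index} must be >= 0")
            if missing > sites:
                raise ValueError(
                    f"layer {index} has {sites} attachment sites, "
                    f"cannot miss {missing}"
                )
            sites *= block.multiplicity
        if self.missing_caps > sites:
            raise ValueError(
                f"only {sites} peripheral sites, cannot miss "
                f"{self.missing_caps} caps"
            )

    @property
    def composition(self) -> ElementalComposition:
        """Perfect composition minus the missing subtrees and caps.

        A missing branch leaves its site as an intact capped (ammonium
        chloride) end group, so per missing branch at layer *i* the
        variant loses the full site contribution but keeps one cap.
        Additions are accumulated before the single subtraction: the
        retained cap can contain atoms (Cl) that the perfect site lost
        during coupling.  Mixed defects compose additively; a zero-defect
        variant equals the perfect structure.
        """
        added = elemental_composition(self.base)
        removed = EMPTY
        for index, missing in self.missing_branches.items():
            if missing:
                assert self.base.cap is not None
                added = added + missing * self.base.cap.composition
                removed = removed + missing * _site_contribution(
                    self.base, index
                )
        if self.missing_caps:
            removed = removed + self.missing_caps * _terminal_contribution(
                self.base
            )
        return added - removed

    @property
    def average_mass(self) -> float:
        return self.composition.average_mass


def defect_ladder(
    spec: DendrimerSpec, max_missing_caps: int
) -> list[tuple[DefectVariant, float]]:
    """Mass ladder of cap-defect variants, sorted by descending mass.

    Rung *k* sits at ``perfect_mass - k * cap_mass``: the arithmetic
    ladder read off mass spectra to estimate end-group completeness
    (the synthesised compounds showed <1-2% missing end groups).
    """
    if spec.terminal_form != "ammonium":
        raise ValueError("defect ladders apply to ammonium-form species")
    n_pg = peripheral_group_count(spec)
    if max_missing_caps < 0:
        raise ValueError("max_missing_caps must be >= 0")
    if max_missing_caps > n_pg:
        raise ValueError(
            f"max_missing_caps={max_missing_caps} exceeds the "
            f"{n_pg} peripheral sites"
        )
    ladder = []
    for k in range(max_missing_caps + 1):
        variant = DefectVariant(base=spec, missing_caps=k)
        ladder.append((variant, variant.average_mass))
    return ladder


# ---------------------------------------------------------------------------
# SMILES export


class SmilesUnsupportedError(RuntimeError):
    """A block lacks the substructure annotation needed for SMILES export."""


def smiles(spec: DendrimerSpec) -> str:
    """Linear molecular encoding of the perfect structure.

    Assembled recursively from the registry's attachment-annotated
    fragments; ammonium termini contribute one chloride counterion each
    (appended as separate components).  Atom counts equal
    :func:`elemental_composition` by construction; tests audit this with
    an external parser.
    """
    def terminal_arm(parent: BuildingBlock) -> str:
        if spec.terminal_form == "allyl":
            return parent.terminal_smiles
        cap = spec.cap
        assert cap is not None
        if cap.smiles_arm is None or cap.smiles_head is None:
            raise SmilesUnsupportedError(
                f"cap {cap.name!r} lacks SMILES arm/head annotations"
            )
        return cap.smiles_arm + cap.smiles_head

    def layer_arm(index: int, parent: BuildingBlock) -> str:
        if index == len(spec.layers):
            return terminal_arm(parent)
        block = spec.layers[index]
        if block.smiles_fragment is None:
            raise SmilesUnsupportedError(
                f"block {block.name!r} lacks a SMILES fragment annotation"
            )
        cap = spec.cap
        if cap is None or cap.smiles_arm is None:
            raise SmilesUnsupportedError(
                "amide-linked layers need the cap's SMILES arm annotation"
            )
        # thioether tether from the TEC cap + amide bond + block aryl body
        arm = layer_arm(index + 1, block)
        return cap.smiles_arm + "NC(=O)" + block.smiles_fragment.format(a=arm)

    core = spec.core
    if core.smiles_fragment is None:
        raise SmilesUnsupportedError(
            f"core {core.name!r} lacks a SMILES fragment annotation"
        )
    body = core.smiles_fragment.format(a=layer_arm(0, core))
    # one counterion per charged terminus, appended as separate components
    if spec.terminal_form == "ammonium" and spec.cap.smiles_counterion:
        n_ions = peripheral_group_count(spec)
        return ".".join([body] + [spec.cap.smiles_counterion] * n_ions)
    return body
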