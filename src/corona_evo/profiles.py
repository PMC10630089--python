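"""Species × trait presence/absence/unknown profiles and co-occurrence statistics.

A :class:`TraitProfile` holds a matrix over the three states ``"1"``
(present), ``"0"`` (absent) and ``"?"`` (unknown).  Traits come in two kinds:
a protein-family trait (is any ortholog of the family encoded in the
species?) and, for prenylated families, a dependent CAAX trait (does any
complete ortholog carry the motif?).  A CAAX trait can never be present when
its host family is absent.

Unknown states are excluded pairwise from all statistics rather than
imputed: a "?" withholds judgment, and because species are phylogenetically
non-independent no significance test is attached — association is summarized
by the phi coefficient only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .caax import CaaxCall

__all__ = [
    "STATES",
    "TraitProfile",
    "CooccurrenceReport",
    "build_profile",
    "cooccurrence",
    "module_coherence",
    "fixture_profile",
    "CORONA_TRAITS",
]

STATES = ("1", "0", "?")

# Canonical trait ordering for the corona gene set.
CORONA_TRAITS = (
    "CENP-E",
    "CENP-E-CAAX",
    "SPINDLY",
    "SPINDLY-CAAX",
    "ROD",
    "ZWILCH",
    "ZW10",
)


@dataclass
class TraitProfile:
    """Ordered species × trait state matrix over {1, 0, ?}."""

    matrix: pd.DataFrame  # index = species, columns = traits, dtype str

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise ValueError(f"species listed twice: {dupes}")
        self.matrix = self.matrix.astype(str)
        bad = set(np.unique(self.matrix.to_numpy())) - set(STATES)
        if bad:
            raise ValueError(f"invalid profile states: {sorted(bad)}")
        self._check_caax_constraint()

    def _check_caax_constraint(self) -> None:
        for trait in self.matrix.columns:
            host = _host_trait(trait)
            if host is None or host not in self.matrix.columns:
                continue
            bad = (self.matrix[trait] == "1") & (self.matrix[host] == "0")
            if bad.any():
                raise ValueError(
                    f"CAAX trait {trait!r} present with host {host!r} absent in "
                    f"{self.matrix.index[bad].tolist()}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def traits(self) -> list[str]:
        return list(self.matrix.columns)

    def restrict(self, species: Sequence[str]) -> "TraitProfile":
        return TraitProfile(self.matrix.loc[list(species)].copy())

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="species", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "TraitProfile":
        frame = pd.read_csv(path, sep="\t", index_col="species", dtype=str, keep_default_na=False)
        return cls(frame)


def _host_trait(trait: str) -> Optional[str]:
    return trait[: -len("-CAAX")] if trait.endswith("-CAAX") else None


def build_profile(
    calls: Mapping[str, Mapping[str, Sequence[CaaxCall]]],
    species_order: Sequence[str],
    families: Sequence[str],
    caax_families: Sequence[str] = ("CENP-E", "SPINDLY"),
) -> TraitProfile:
    """Collapse per-protein CAAX calls into a species × trait profile.

    ``calls[species][family]`` is the list of calls for every detected
    ortholog of that family in that species (possibly empty or missing when
    the family is absent).  Presence collapses by "any ortholog"; the CAAX
    trait collapses by "any complete CAAX-positive ortholog", is 0 when every
    complete ortholog is CAAX-negative, and "?" when the family is present
    but only fragments (or −4 ambiguity) are available.  A CAAX trait is
    forced to 0 wherever the host family is absent.
    """
    if len(set(species_order)) != len(species_order):
        dupes = [s for s in species_order if list(species_order).count(s) > 1]
        raise ValueError(f"species listed twice: {sorted(set(dupes))}")
    columns: list[str] = []
    for family in families:
        columns.append(family)
        if family in caax_families:
            columns.append(f"{family}-CAAX")
    rows = {}
    for sp in species_order:
        row = {}
        per_family = calls.get(sp, {})
        for family in families:
            family_calls = list(per_family.get(family, ()))
            present = len(family_calls) > 0
            row[family] = "1" if present else "0"
            if family in caax_families:
                trait = f"{family}-CAAX"
                if not present:
                    row[trait] = "0"
                elif any(c.state == "present" for c in family_calls):
                    row[trait] = "1"
                elif all(c.state == "unknown" for c in family_calls):
                    row[trait] = "?"
                elif any(c.state == "absent" for c in family_calls):
                    row[trait] = "0"
                else:  # pragma: no cover - exhaustive above
                    row[trait] = "?"
        rows[sp] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index").loc[list(species_order), columns]
    return TraitProfile(matrix)


@dataclass
class CooccurrenceReport:
    trait_a: str
    trait_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    excluded_unknown: int
    agreement: Optional[float]
    phi: Optional[float]  # None when a 2x2 margin is empty (undefined)


def cooccurrence(profile: TraitProfile, trait_a: str, trait_b: str) -> CooccurrenceReport:
    """2×2 co-occurrence of two traits, excluding species unknown in either.

    Agreement is (both + neither) / included; association is the phi
    coefficient of the 2×2 table, reported as ``None`` (undefined) when a
    margin is zero.
    """
    for trait in (trait_a, trait_b):
        if trait not in profile.traits:
            raise KeyError(f"trait {trait!r} not in profile")
    a = profile.matrix[trait_a]
    b = profile.matrix[trait_b]
    included = (a != "?") & (b != "?")
    n_excluded = int((~included).sum())
    a_in = a[included] == "1"
    b_in = b[included] == "1"
    both = int((a_in & b_in).sum())
    a_only = int((a_in & ~b_in).sum())
    b_only = int((~a_in & b_in).sum())
    neither = int((~a_in & ~b_in).sum())
    n = both + a_only + b_only + neither
    agreement = (both + neither) / n if n > 0 else None
    phi: Optional[float] = None
    if n >= 2:
        margins = [
            (both + a_only),
            (b_only + neither),
            (both + b_only),
            (a_only + neither),
        ]
        if all(m > 0 for m in margins):
            phi = (both * neither - a_only * b_only) / float(
                np.sqrt(np.prod([float(m) for m in margins]))
            )
    return CooccurrenceReport(
        trait_a=trait_a,
        trait_b=trait_b,
        both=both,
        a_only=a_only,
        b_only=b_only,
        neither=neither,
        excluded_unknown=n_excluded,
        agreement=agreement,
        phi=phi,
    )


@dataclass
class CoherenceReport:
    traits: tuple[str, ...]
    coherence: Optional[float]
    incoherent_species: list[str]
    excluded_unknown: int


def module_coherence(profile: TraitProfile, traits: Sequence[str]) -> CoherenceReport:
    """Fraction of species that are all-present or all-absent across ``traits``.

    Species unknown in any of the traits are excluded.  Returns the coherence
    value in [0, 1] plus the list of incoherent (mixed-state) species.
    """
    traits = tuple(traits)
    if not traits:
        raise ValueError("module_coherence requires at least one trait")
    if len(traits) < 2:
        raise ValueError("module_coherence requires at least two traits")
    for trait in traits:
        if trait not in profile.traits:
            raise KeyError(f"trait {trait!r} not in profile")
    sub = profile.matrix[list(traits)]
    included = ~(sub == "?").any(axis=1)
    sub = sub[included]
    if sub.empty:
        return CoherenceReport(traits, None, [], int((~included).sum()))
    all_present = (sub == "1").all(axis=1)
    all_absent = (sub == "0").all(axis=1)
    coherent = all_present | all_absent
    return CoherenceReport(
        traits=traits,
        coherence=float(coherent.mean()),
        incoherent_species=sub.index[~coherent].tolist(),
        excluded_unknown=int((~included).sum()),
    )


def fixture_profile() -> TraitProfile:
    """The packaged qualitative corona-gene profile over ten eukaryote lineages.

    Encodes the field's consensus picture: ZW10 (with its trafficking role)
    and the kinesin-7 CENP-E family are found across all major lineages;
    ROD/ZWILCH extend to the Stramenopila/Alveolata; SPINDLY and its CAAX box
    are confined to Obazoa; and a CAAX box on CENP-E occurs in two distantly
    related groups (Opisthokonta/Apusozoa and Stramenopila/Alveolata), with
    the fragmentary Breviata data rendered unknown.
    """
    species = [
        "Opisthokonta",
        "Apusozoa",
        "Breviata",
        "Amoebozoa",
        "Archaeplastida",
        "Discoba",
        "Metamonada",
        "Stramenopila",
        "Alveolata",
        "Rhizaria",
    ]
    ones = {sp: "1" for sp in species}
    data = {
        "CENP-E": ones.copy(),
        "CENP-E-CAAX": {
            "Opisthokonta": "1",
            "Apusozoa": "1",
            "Breviata": "?",
            "Stramenopila": "1",
            "Alveolata": "1",
        },
        "SPINDLY": {"Opisthokonta": "1", "Apusozoa": "1", "Breviata": "1"},
        "SPINDLY-CAAX": {"Opisthokonta": "1", "Apusozoa": "1", "Breviata": "?"},
        "ROD": {
            "Opisthokonta": "1",
            "Apusozoa": "1",
            "Breviata": "1",
            "Stramenopila": "1",
            "Alveolata": "1",
        },
        "ZWILCH": {
            "Opisthokonta": "1",
            "Apusozoa": "1",
            "Breviata": "1",
            "Stramenopila": "1",
            "Alveolata": "1",
        },
        "ZW10": ones.copy(),
    }
    matrix = pd.DataFrame("0", index=species, columns=list(CORONA_TRAITS))
    for trait, cells in data.items():
        for sp, state in cells.items():
            matrix.loc[sp, trait] = state
    return TraitProfile(matrix)


def plot_profile(profile: TraitProfile, path) -> None:
    """Render the matrix as colored (present) / white (absent) squares.

    Unknown cells are drawn hatched with a question mark.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = profile.matrix
    n_sp, n_tr = mat.shape
    fig, ax = plt.subplots(figsize=(0.5 * n_tr + 2, 0.35 * n_sp + 1.5))
    for i, sp in enumerate(mat.index):
        for j, trait in enumerate(mat.columns):
            state = mat.loc[sp, trait]
            color = {"1": "#3b6fb6", "0": "white", "?": "#dddddd"}[state]
            ax.add_patch(plt.Rectangle((j, n_sp - 1 - i), 1, 1, facecolor=color, edgecolor="black"))
            if state == "?":
                ax.text(j + 0.5, n_sp - 0.5 - i, "?", ha="center", va="center", fontsize=8)
    ax.set_xlim(0, n_tr)
    ax.set_ylim(0, n_sp)
    ax.set_xticks([j + 0.5 for j in range(n_tr)])
    ax.set_xticklabels(mat.columns, rotation=90)
    ax.set_yticks([n_sp - 0.5 - i for i in range(n_sp)])
    ax.set_yticklabels(mat.index)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
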