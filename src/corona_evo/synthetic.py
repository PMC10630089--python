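"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators are provided:

* :func:`simulate_trait_history` — presence/absence evolution of one trait
  on a rooted tree.  The branch process is a per-edge Bernoulli trial (a
  gain when the parent lacks the trait, a loss when it has it), which matches
  the discrete per-lineage granularity at which gene-content evolution is
  reasoned about and keeps the event bookkeeping exact.  ``dollo_mode``
  restricts the whole history to at most one gain.

* :func:`emit_proteomes` — per-species protein FASTA records consistent with
  a trait profile.  Each family carries a distinctive internal seed motif
  (the handle for ortholog assignment), a CAAX-positive ortholog ends with a
  four-residue motif whose −4 residue is C, a CAAX-negative one has no C at
  −4, and fragment exemplars are C-terminally truncated and flagged
  ``partial=true``.  Decoy background proteins (uniform residues, never C at
  −4) are added per species.

* :func:`simulate_intensity_table` — TurboID-style log2 protein intensity
  tables with replicate structure, planted enriched proteins, unique-peptide
  counts, and missing-not-at-random dropout: the probability that a value is
  missing is a decreasing logistic function of the true log-intensity.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .caax import AMINO_ACIDS, ProteinRecord
from .proteomics import IntensityTable
from .trees import Tree

__all__ = [
    "SimulatedHistory",
    "FamilySpec",
    "DropoutModel",
    "simulate_trait_history",
    "emit_proteomes",
    "assign_orthologs",
    "simulate_intensity_table",
    "default_family_specs",
]


@dataclass
class SimulatedHistory:
    """A trait history: per-node states, the exact event list, and leaf states."""

    node_states: dict[str, int]
    events: list[tuple[str, str]]  # (child-node name, "gain"|"loss")
    leaf_states: dict[str, int]
    seed: int


def simulate_trait_history(
    tree: Tree,
    gain_rate: float,
    loss_rate: float,
    root_state: int = 0,
    dollo_mode: bool = False,
    seed: int = 0,
) -> SimulatedHistory:
    """Simulate presence/absence evolution with per-edge Bernoulli events."""
    for name, rate in (("gain_rate", gain_rate), ("loss_rate", loss_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    if root_state not in (0, 1):
        raise ValueError(f"root_state must be 0 or 1, got {root_state}")
    rng = np.random.default_rng(seed)
    node_states: dict[str, int] = {tree.root.name: root_state}
    events: list[tuple[str, str]] = []
    gain_spent = dollo_mode and root_state == 1
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_state = node_states[node.parent.name]
        state = parent_state
        if parent_state == 0:
            allowed = not (dollo_mode and gain_spent)
            if allowed and rng.random() < gain_rate:
                state = 1
                events.append((node.name, "gain"))
                if dollo_mode:
                    gain_spent = True
        else:
            if rng.random() < loss_rate:
                state = 0
                events.append((node.name, "loss"))
        node_states[node.name] = state
    leaf_states = {leaf.name: node_states[leaf.name] for leaf in tree.leaves()}
    return SimulatedHistory(node_states, events, leaf_states, seed)


@dataclass
class FamilySpec:
    """Generation recipe for one ortholog family."""

    name: str
    seed_motif: str  # distinctive internal tag used for ortholog assignment
    length_range: tuple[int, int] = (300, 500)
    caax_motif: str = "CKTQ"
    has_caax_trait: bool = False


def default_family_specs() -> dict[str, FamilySpec]:
    """Corona gene set with distinctive seed motifs and realistic size ranges."""
    return {
        "CENP-E": FamilySpec("CENP-E", "WHDMEKWQH", (600, 900), "CKTQ", True),
        "SPINDLY": FamilySpec("SPINDLY", "YQDLSPWYR", (450, 650), "CAQL", True),
        "ROD": FamilySpec("ROD", "FNRPDWHYK", (700, 1000)),
        "ZWILCH": FamilySpec("ZWILCH", "MHWEYDQRV", (350, 550)),
        "ZW10": FamilySpec("ZW10", "KYWQHDPEM", (500, 700)),
    }


def _random_residues(rng: np.random.Generator, length: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)]


def _non_caax_terminus(rng: np.random.Generator) -> list[str]:
    tail = _random_residues(rng, 4)
    while tail[0] == "C":
        tail[0] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
    return tail


def _family_sequence(
    rng: np.random.Generator, spec: FamilySpec, caax_state: str
) -> tuple[str, bool]:
    """Return (sequence, is_fragment) for one ortholog."""
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    residues = _random_residues(rng, length)
    mid = length // 2
    residues[mid : mid + len(spec.seed_motif)] = list(spec.seed_motif)
    if caax_state == "1":
        residues[-4:] = list(spec.caax_motif)
    else:
        residues[-4:] = _non_caax_terminus(rng)
    if caax_state == "?":
        # fragment: truncate before the terminal motif so the call is unknown
        cut = int(rng.integers(mid + len(spec.seed_motif), length - 9))
        return "".join(residues[:cut]), True
    return "".join(residues), False


def emit_proteomes(
    profile,
    family_specs: Mapping[str, FamilySpec],
    fragment_fraction: float = 0.0,
    seed: int = 0,
    n_decoys: int = 20,
    decoy_length_range: tuple[int, int] = (150, 400),
) -> tuple[dict[str, list[ProteinRecord]], pd.DataFrame]:
    """Emit per-species protein records consistent with a trait profile.

    For every (species, family) cell: present-with-CAAX orthologs end in the
    family's CAAX motif, present-without-CAAX orthologs have no C at −4,
    unknown-CAAX cells are emitted as flagged fragments, and absent cells
    emit nothing.  ``fragment_fraction`` additionally truncates that
    proportion of definite-state orthologs (their truth-table CAAX state is
    retained).  Returns the records per species plus a machine-readable
    truth table.
    """
    if not (0.0 <= fragment_fraction <= 1.0):
        raise ValueError("fragment_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    proteomes: dict[str, list[ProteinRecord]] = {}
    truth_rows = []
    for sp in profile.species:
        records: list[ProteinRecord] = []
        for family in profile.traits:
            if family.endswith("-CAAX") or family not in family_specs:
                continue
            spec = family_specs[family]
            presence = profile.matrix.loc[sp, family]
            if presence == "?":
                raise ValueError(
                    f"unknown presence state for ({sp}, {family}); presence must be 0 or 1"
                )
            if presence == "0":
                truth_rows.append(
                    {"species": sp, "family": family, "present": 0, "caax": "0", "fragment": 0}
                )
                continue
            caax_trait = f"{family}-CAAX"
            caax_state = (
                profile.matrix.loc[sp, caax_trait] if caax_trait in profile.traits else "0"
            )
            seq, is_fragment = _family_sequence(rng, spec, caax_state)
            if not is_fragment and fragment_fraction > 0 and rng.random() < fragment_fraction:
                # truncate after the seed motif but before the terminal 4-mer
                lo = len(seq) // 2 + len(spec.seed_motif)
                cut = int(rng.integers(lo, len(seq) - 9))
                seq = seq[:cut]
                is_fragment = True
            protein_id = f"{sp}_{family}_1"
            records.append(
                ProteinRecord(
                    protein_id=protein_id,
                    species=sp,
                    family=family,
                    sequence=seq,
                    partial_flag=True if is_fragment else False,
                )
            )
            truth_rows.append(
                {
                    "species": sp,
                    "family": family,
                    "present": 1,
                    "caax": caax_state,
                    "fragment": int(is_fragment),
                }
            )
        motifs = [s.seed_motif for s in family_specs.values()]
        for d in range(n_decoys):
            length = int(rng.integers(decoy_length_range[0], decoy_length_range[1] + 1))
            residues = _random_residues(rng, length)
            residues[-4:] = _non_caax_terminus(rng)
            seq = "".join(residues)
            while any(m in seq for m in motifs):  # vanishingly rare; keep decoys clean
                residues = _random_residues(rng, length)
                residues[-4:] = _non_caax_terminus(rng)
                seq = "".join(residues)
            records.append(
                ProteinRecord(
                    protein_id=f"{sp}_decoy_{d + 1}",
                    species=sp,
                    family="decoy",
                    sequence=seq,
                    partial_flag=False,
                )
            )
        proteomes[sp] = records
    truth = pd.DataFrame(truth_rows, columns=["species", "family", "present", "caax", "fragment"])
    return proteomes, truth


def assign_orthologs(
    records: Sequence[ProteinRecord], family_specs: Mapping[str, FamilySpec]
) -> dict[str, list[ProteinRecord]]:
    """Assign records to families by their internal seed motif.

    This tag/motif-based assigner stands in for profile-HMM homology searches
    on real proteomes: each synthetic family carries a distinctive internal
    motif, so containment is a faithful (and exactly checkable) analogue.
    """
    assigned: dict[str, list[ProteinRecord]] = {name: [] for name in family_specs}
    for record in records:
        for name, spec in family_specs.items():
            if spec.seed_motif in record.sequence:
                assigned[name].append(record)
                break
    return assigned


@dataclass
class DropoutModel:
    """Missing-not-at-random dropout, logistic in the true log2 intensity.

    P(missing | x) = 1 / (1 + exp(steepness * (x - midpoint))): values far
    below the midpoint are almost always missing, far above almost never.
    """

    midpoint: float = 22.0
    steepness: float = 1.5

    def p_missing(self, x: np.ndarray) -> np.ndarray:
        z = np.clip(self.steepness * (np.asarray(x, dtype=float) - self.midpoint), -700, 700)
        return 1.0 / (1.0 + np.exp(z))


def simulate_intensity_table(
    n_proteins: int,
    n_enriched: int,
    effect_log2: float = 4.0,
    n_reps: int = 3,
    dropout_model: Optional[DropoutModel] = None,
    seed: int = 0,
    condition_a: str = "WT",
    condition_b: str = "emp",
    base_mean: float = 26.0,
    base_sd: float = 2.0,
    replicate_sd: float = 0.4,
) -> tuple[IntensityTable, pd.DataFrame]:
    """Simulate a protein × sample log2 intensity table with planted enrichment.

    The first ``n_enriched`` proteins gain ``effect_log2`` in condition
    ``condition_a``.  Per-replicate noise is Gaussian; unique-peptide counts
    are Poisson (so a few zeros exercise the peptide filter); dropout, when
    enabled, follows the logistic MNAR model on the true cell intensity.
    Returns the table plus a truth frame flagging the planted proteins.
    """
    if n_proteins <= 0 or n_reps <= 0:
        raise ValueError("n_proteins and n_reps must be positive")
    if n_enriched < 0 or n_enriched > n_proteins:
        raise ValueError("n_enriched must lie in [0, n_proteins]")
    if n_reps < 2:
        raise ValueError("at least two replicates per condition are required")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    enriched = np.zeros(n_proteins, dtype=bool)
    enriched[:n_enriched] = True

    base = rng.normal(base_mean, base_sd, size=n_proteins)
    mean_a = base + np.where(enriched, effect_log2, 0.0)
    mean_b = base

    samples, conditions, replicates, columns = [], [], [], []
    for cond, means in ((condition_a, mean_a), (condition_b, mean_b)):
        for rep in range(1, n_reps + 1):
            values = rng.normal(means, replicate_sd)
            if dropout_model is not None:
                missing = rng.random(n_proteins) < dropout_model.p_missing(values)
                values = np.where(missing, np.nan, values)
            samples.append(f"{cond}_{rep}")
            conditions.append(cond)
            replicates.append(rep)
            columns.append(values)

    values = pd.DataFrame(
        np.column_stack(columns), index=proteins, columns=samples
    )
    design = pd.DataFrame(
        {"sample": samples, "condition": conditions, "replicate": replicates}
    )
    unique_peptides = pd.Series(rng.poisson(5, size=n_proteins), index=proteins)
    table = IntensityTable(
        values=values, design=design, unique_peptides=unique_peptides, scale="log2"
    )
    truth = pd.DataFrame({"protein": proteins, "enriched": enriched.astype(int)})
    return table, truth
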