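"""CAAX prenylation-motif inference and construct building.

A CAAX box is a C-terminal four-residue motif whose first residue is the
prenyl-acceptor cysteine; operationally a protein is CAAX-positive when the
residue at offset −4 from the C-terminus (the terminal residue counts as −1)
is a cysteine.  Calls are three-state: ``present``, ``absent`` or ``unknown``.
An ``unknown`` call is made for fragmentary records — C-terminally truncated
predictions for which the true terminus, and hence the motif, cannot be
observed — and for sequences whose −4 residue is the ambiguity code X.

The module also includes a deletion/substitution construct builder used for
worked examples on kinesin-7 (CENP-E) and SPINDLY mutants: C-terminal
truncations, alanine-scanning windows, acceptor-cysteine point mutants and
CAAX-box swaps (e.g. onto the KRAS4b motif Cys-Ile-Ile-Met).

Coordinates are 1-based inclusive throughout; negative offsets count from the
C-terminus with the terminal residue at −1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "CaaxCall",
    "ConstructSpec",
    "ConstructReport",
    "detect_caax",
    "assess_completeness",
    "build_construct",
    "synthetic_cenp_e_parent",
    "synthetic_spindly_parent",
    "cenp_e_construct_specs",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = set(AMINO_ACIDS) | {"X", "*"}

CompletenessVerdict = Literal["complete", "fragment"]
CaaxState = Literal["present", "absent", "unknown"]


@dataclass
class ProteinRecord:
    """One predicted protein.

    ``partial_flag`` is tri-state: ``True`` (annotated as a fragment),
    ``False`` (annotated full-length) or ``None`` (unstated, so completeness
    must be judged heuristically).
    """

    protein_id: str
    species: str
    family: str
    sequence: str
    partial_flag: Optional[bool] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        bad = set(self.sequence.upper()) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"invalid residues {sorted(bad)} in protein {self.protein_id!r}"
            )
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CaaxCall:
    state: CaaxState
    acceptor_position_1based: Optional[int] = None
    acceptor_offset_from_C: Optional[int] = None
    motif: Optional[str] = None


def assess_completeness(
    record: ProteinRecord,
    family_median_length: Optional[float] = None,
    min_length_fraction: float = 0.5,
) -> CompletenessVerdict:
    """Judge whether a record is full-length or a C-terminally deficient fragment.

    An explicit ``partial_flag`` always wins.  With the flag unstated the
    heuristic calls a fragment when the sequence is shorter than
    ``min_length_fraction`` of the family's median length, or when the
    sequence ends in an ambiguity/truncation marker (a trailing X after
    stripping stop characters).  With no evidence of fragmentation the record
    fails open to ``complete``.
    """
    if record.partial_flag is True:
        return "fragment"
    if record.partial_flag is False:
        return "complete"
    seq = record.sequence.rstrip("*")
    if seq.endswith("X"):
        return "fragment"
    if family_median_length is not None and family_median_length > 0:
        if len(seq) < min_length_fraction * family_median_length:
            return "fragment"
    return "complete"


def detect_caax(
    record: ProteinRecord,
    family_median_length: Optional[float] = None,
    min_length_fraction: float = 0.5,
) -> CaaxCall:
    """Three-state CAAX call: cysteine at offset −4 from the C-terminus.

    Fragmentary records (per :func:`assess_completeness`) are ``unknown``
    because their true terminus is unobserved.  Trailing stop characters are
    stripped before scanning; an X at the −4 position is ``unknown``.  Only
    the cysteine rule is enforced — the three downstream residues are
    unconstrained.
    """
    verdict = assess_completeness(record, family_median_length, min_length_fraction)
    if verdict == "fragment":
        return CaaxCall(state="unknown")
    seq = record.sequence.rstrip("*")
    if not seq:
        raise ValueError(f"protein {record.protein_id!r} has no residues after '*' stripping")
    if len(seq) < 4:
        logger.warning(
            "protein %s is complete but shorter than 4 residues; calling CAAX absent",
            record.protein_id,
        )
        return CaaxCall(state="absent")
    acceptor = seq[-4]
    if acceptor == "X":
        return CaaxCall(state="unknown")
    if acceptor == "C":
        return CaaxCall(
            state="present",
            acceptor_position_1based=len(seq) - 3,
            acceptor_offset_from_C=-4,
            motif=seq[-4:],
        )
    return CaaxCall(state="absent")


@dataclass
class ConstructSpec:
    """A truncation/substitution construct in parent coordinates.

    ``start``/``end`` delimit the construct (1-based inclusive).
    ``substitutions`` is a list of ``(win_start, win_end, residue)`` windows in
    parent coordinates, each replaced by the given single residue.
    ``caax_swap`` replaces the construct's final four residues.
    """

    name: str
    start: int
    end: int
    substitutions: list[tuple[int, int, str]] = field(default_factory=list)
    caax_swap: Optional[str] = None


@dataclass
class ConstructReport:
    name: str
    length: int
    n_substituted_positions: int
    removed_n_terminal: int
    removed_c_terminal: int


def build_construct(
    parent_sequence: str, spec: ConstructSpec, species: str = "synthetic", family: str = "construct"
) -> tuple[ProteinRecord, ConstructReport]:
    """Apply a :class:`ConstructSpec` to a parent sequence.

    Returns the construct as a full-length (``partial_flag=False``) record plus
    a report of its length, the number of positions differing from the parent
    over the retained window, and the residues removed from each terminus.
    """
    parent = parent_sequence.upper()
    length = len(parent)
    if not (1 <= spec.start <= spec.end <= length):
        raise ValueError(
            f"construct window {spec.start}-{spec.end} invalid for parent of length {length}"
        )
    residues = list(parent)
    for win_start, win_end, replacement in spec.substitutions:
        if not (spec.start <= win_start <= win_end <= spec.end):
            raise ValueError(
                f"substitution window {win_start}-{win_end} outside construct "
                f"{spec.start}-{spec.end}"
            )
        if len(replacement) != 1 or replacement.upper() not in set(AMINO_ACIDS):
            raise ValueError(f"replacement must be one amino acid, got {replacement!r}")
        for pos in range(win_start, win_end + 1):
            residues[pos - 1] = replacement.upper()
    construct = residues[spec.start - 1 : spec.end]
    if spec.caax_swap is not None:
        if len(construct) < 4:
            raise ValueError("caax_swap requires a construct of at least 4 residues")
        swap = spec.caax_swap.upper()
        if len(swap) != 4 or set(swap) - set(AMINO_ACIDS):
            raise ValueError(f"caax_swap must be a 4-residue motif, got {spec.caax_swap!r}")
        construct[-4:] = list(swap)
    sequence = "".join(construct)
    window_parent = parent[spec.start - 1 : spec.end]
    n_diff = sum(1 for a, b in zip(sequence, window_parent) if a != b)
    record = ProteinRecord(
        protein_id=spec.name,
        species=species,
        family=family,
        sequence=sequence,
        partial_flag=False,
    )
    report = ConstructReport(
        name=spec.name,
        length=len(sequence),
        n_substituted_positions=n_diff,
        removed_n_terminal=spec.start - 1,
        removed_c_terminal=length - spec.end,
    )
    return record, report


def _random_protein(length: int, rng, terminal: str | None = None) -> str:
    import numpy as np  # local import keeps module import light

    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    seq = "".join(AMINO_ACIDS[i] for i in np.asarray(idx))
    if terminal is not None:
        seq = seq[: length - len(terminal)] + terminal
    return seq


def synthetic_cenp_e_parent(length: int = 2701, seed: int = 0) -> str:
    """Synthetic stand-in for a full-length human kinesin-7 (CENP-E) sequence.

    Random residues at the stated full length, ending in the CKTQ CAAX box so
    the acceptor cysteine sits at position ``length − 3`` (2698 for the
    default).  This is a synthetic sequence for coordinate arithmetic and
    scanner tests, not the real protein.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    seq = _random_protein(length, rng, terminal="CKTQ")
    # keep the body C-free at −4-adjacent coordinates deterministic enough:
    return seq


def synthetic_spindly_parent(length: int = 605, seed: int = 0) -> str:
    """Synthetic stand-in for a full-length SPINDLY sequence ending in a CAAX box.

    The acceptor cysteine sits at ``length − 3`` (602 for the default), which
    is the residue mutated in the classic non-farnesylatable C602A variant.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    return _random_protein(length, rng, terminal="CAQL")


def cenp_e_construct_specs() -> dict[str, ConstructSpec]:
    """The CENP-E C-terminal construct panel used in the worked examples.

    2111-C is the C-terminal fragment (2111–2701) sufficient for corona
    formation; 2111–2689 removes the last 12 residues (including the CAAX
    box); 2111–2643 truncates the C-terminal 58 residues; C-10A1..C-10A9 are
    ten-residue alanine-scanning windows; C2698A and Q2701A mutate the CAAX
    box; the KRAS4b swap replaces the terminal motif with CIIM.
    """
    specs: dict[str, ConstructSpec] = {
        "2111-C": ConstructSpec("2111-C", 2111, 2701),
        "2111-2689": ConstructSpec("2111-2689", 2111, 2689),
        "2111-2643": ConstructSpec("2111-2643", 2111, 2643),
        "C2698A": ConstructSpec("C2698A", 2111, 2701, substitutions=[(2698, 2698, "A")]),
        "Q2701A": ConstructSpec("Q2701A", 2111, 2701, substitutions=[(2701, 2701, "A")]),
        "CAAX-KRAS4b": ConstructSpec("CAAX-KRAS4b", 2111, 2697, caax_swap="CIIM"),
    }
    for i in range(9):
        win_start = 2600 + 10 * i
        specs[f"C-10A{i + 1}"] = ConstructSpec(
            f"C-10A{i + 1}", 2111, 2701, substitutions=[(win_start, win_start + 9, "A")]
        )
    return specs
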