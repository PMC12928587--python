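"""Structural annotations: records, DSSP reduction, CATH labels, partitions, splits.

A protein domain is represented by a :class:`DomainRecord` carrying its
amino-acid sequence, an optional CATH classification string ("C.A.T.H"
dotted integers) and an optional per-residue 3-state secondary-structure
string over ``{H, E, L}`` (helix, strand, loop).  A
:class:`SuppressionSpec` names the structural category whose language-model
predictability a subnetwork should destroy, either a whole category of
sequences (one truncated CATH label) or one residue state; the induced
suppression/maintenance partition is built by :func:`build_partition`.

Positions are 0-based everywhere in memory; TSV reports written by
:mod:`plmsubnet.io` use 1-based positions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "NONCANONICAL",
    "AnnotationError",
    "ConfigError",
    "CathLevel",
    "DomainRecord",
    "SuppressionSpec",
    "SplitAssignment",
    "Partition",
    "reduce_dssp",
    "truncate_cath",
    "build_partition",
    "filter_by_length",
    "split_dataset",
    "sanitize_records",
]

#: The canonical 20-letter amino-acid alphabet (alphabetical one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Noncanonical one-letter codes occasionally present in real sequence data.
NONCANONICAL = "XBZUO"

SS3_STATES = "HEL"

_DSSP_REDUCTION = {
    "H": "H", "G": "H", "I": "H",   # helix types
    "E": "E", "B": "E",             # strand / bridge
    "T": "L", "S": "L", "-": "L",   # turns, bends, coil
}


class AnnotationError(ValueError):
    """An annotation string or label violates its format contract."""


class ConfigError(ValueError):
    """A configuration value is out of its permitted range."""


class CathLevel(enum.Enum):
    """The four levels of the CATH hierarchy, coarsest to finest."""

    CLASS = 1
    ARCHITECTURE = 2
    TOPOLOGY = 3
    HOMOLOGOUS_SUPERFAMILY = 4


@dataclass(frozen=True)
class DomainRecord:
    """One protein domain: sequence plus optional structural annotations."""

    id: str
    sequence: str
    cath_label: str | None = None
    ss3: str | None = None

    def __post_init__(self):
        if self.ss3 is not None and len(self.ss3) != len(self.sequence):
            raise AnnotationError(
                f"record {self.id!r}: ss3 length {len(self.ss3)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.ss3 is not None:
            bad = set(self.ss3) - set(SS3_STATES)
            if bad:
                raise AnnotationError(
                    f"record {self.id!r}: ss3 contains non-3-state characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SuppressionSpec:
    """Names the structural category a subnetwork is trained to suppress.

    ``level="sequence"`` suppresses every domain whose CATH label, truncated
    to ``cath_level``, equals ``target_label``; ``level="residue"``
    suppresses every position annotated with the 3-state ``target_label``.
    """

    level: str
    target_label: str
    cath_level: CathLevel | None = None

    def __post_init__(self):
        if self.level not in ("sequence", "residue"):
            raise ConfigError(f"level must be 'sequence' or 'residue', got {self.level!r}")
        if self.level == "residue":
            if self.target_label not in SS3_STATES:
                raise ConfigError(
                    f"residue-level target must be one of {SS3_STATES!r}, "
                    f"got {self.target_label!r}"
                )
        else:
            if self.cath_level is None:
                raise ConfigError("sequence-level spec requires cath_level")
            nfields = len(self.target_label.split("."))
            if nfields != self.cath_level.value:
                raise ConfigError(
                    f"target {self.target_label!r} has {nfields} dotted fields; "
                    f"{self.cath_level.name} requires {self.cath_level.value}"
                )


@dataclass(frozen=True)
class SplitAssignment:
    """Deterministic train/validation/test assignment of record ids."""

    assignment: dict[str, str]
    seed: int

    def ids(self, part: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == part]

    def counts(self) -> dict[str, int]:
        out = {"train": 0, "validation": 0, "test": 0}
        for p in self.assignment.values():
            out[p] += 1
        return out


@dataclass(frozen=True)
class Partition:
    """The suppression/maintenance split induced by a :class:`SuppressionSpec`.

    Sequence level: whole record ids on each side.  Residue level: every
    record participates, with per-record 0-based suppressed positions J*
    (``residue_positions``) and the maintained complement J'.
    """

    level: str
    suppressed_ids: frozenset = field(default_factory=frozenset)
    maintained_ids: frozenset = field(default_factory=frozenset)
    residue_positions: dict[str, np.ndarray] | None = None
    record_lengths: dict[str, int] | None = None

    def suppressed_positions(self, record_id: str) -> np.ndarray:
        if self.level != "residue":
            raise ConfigError("suppressed_positions is defined for residue-level partitions")
        return self.residue_positions[record_id]

    def maintained_positions(self, record_id: str) -> np.ndarray:
        jstar = self.suppressed_positions(record_id)
        n = self.record_lengths[record_id]
        mask = np.ones(n, dtype=bool)
        mask[jstar] = False
        return np.nonzero(mask)[0]


def reduce_dssp(eight_state: str) -> str:
    """Reduce a DSSP 8-state string to 3 states: H,G,I→H; E,B→E; T,S,-→L."""
    out = []
    for pos, ch in enumerate(eight_state):
        try:
            out.append(_DSSP_REDUCTION[ch])
        except KeyError:
            raise AnnotationError(
                f"unknown DSSP character {ch!r} at position {pos}"
            ) from None
    return "".join(out)


def truncate_cath(label: str, level: CathLevel) -> str:
    """Keep the first 1–4 dotted fields of a CATH label, per ``level``."""
    fields = label.split(".")
    need = level.value
    if len(fields) < need:
        raise AnnotationError(
            f"CATH label {label!r} has {len(fields)} fields; "
            f"{level.name} requires {need}"
        )
    for f in fields:
        if not f.isdigit():
            raise AnnotationError(f"CATH label {label!r} has non-integer field {f!r}")
    return ".".join(fields[:need])


def build_partition(records: list[DomainRecord], spec: SuppressionSpec) -> Partition:
    """Split ``records`` into suppression and maintenance sides under ``spec``.

    Sequence level: a record is suppressed iff its CATH label truncated to
    ``spec.cath_level`` equals the target.  Residue level: per record, J* is
    the 0-based positions carrying the target 3-state annotation and J' is
    the complement.  The two sides are disjoint and jointly exhaustive; an
    empty suppression side is an error.
    """
    if spec.level == "sequence":
        missing = [r.id for r in records if r.cath_label is None]
        if missing:
            raise AnnotationError(f"records missing cath_label: {missing}")
        supp, maint = set(), set()
        for r in records:
            if truncate_cath(r.cath_label, spec.cath_level) == spec.target_label:
                supp.add(r.id)
            else:
                maint.add(r.id)
        if not supp:
            raise AnnotationError(
                f"no record matches suppression target {spec.target_label!r}"
            )
        return Partition(
            level="sequence",
            suppressed_ids=frozenset(supp),
            maintained_ids=frozenset(maint),
        )

    missing = [r.id for r in records if r.ss3 is None]
    if missing:
        raise AnnotationError(f"records missing ss3 annotation: {missing}")
    positions = {}
    lengths = {}
    total = 0
    for r in records:
        jstar = np.array(
            [i for i, s in enumerate(r.ss3) if s == spec.target_label], dtype=np.intp
        )
        positions[r.id] = jstar
        lengths[r.id] = len(r)
        total += jstar.size
    if total == 0:
        raise AnnotationError(
            f"no position carries suppression target state {spec.target_label!r}"
        )
    all_ids = frozenset(r.id for r in records)
    return Partition(
        level="residue",
        suppressed_ids=all_ids,
        maintained_ids=all_ids,
        residue_positions=positions,
        record_lengths=lengths,
    )


def filter_by_length(
    records: list[DomainRecord], min_len: int = 64, max_len: int = 1024
) -> list[DomainRecord]:
    """Keep records with ``min_len <= length <= max_len`` (bounds inclusive)."""
    if min_len > max_len:
        raise ConfigError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= len(r) <= max_len]


def split_dataset(
    records: list[DomainRecord],
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
    stratify: bool = False,
) -> SplitAssignment:
    """Randomly split records 70/20/10 (by default) into train/validation/test.

    Validation and test sizes are ``floor(n * fraction)``; the remainder goes
    to train.  With ``stratify=True`` the rule is applied within each CATH
    Class so category frequencies are preserved across partitions.
    """
    ft, fv, fs = fractions
    if min(fractions) <= 0:
        raise ConfigError(f"fractions must be positive, got {fractions}")
    if not math.isclose(ft + fv + fs, 1.0, abs_tol=1e-6):
        raise ConfigError(f"fractions must sum to 1, got {fractions}")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}

    def _assign(group: list[DomainRecord]) -> None:
        ids = [r.id for r in group]
        order = rng.permutation(len(ids))
        n = len(ids)
        n_val = int(n * fv)
        n_test = int(n * fs)
        n_train = n - n_val - n_test
        for rank, idx in enumerate(order):
            if rank < n_train:
                part = "train"
            elif rank < n_train + n_val:
                part = "validation"
            else:
                part = "test"
            assignment[ids[idx]] = part

    if stratify:
        groups: dict[str, list[DomainRecord]] = {}
        for r in records:
            key = (
                truncate_cath(r.cath_label, CathLevel.CLASS)
                if r.cath_label is not None
                else "?"
            )
            groups.setdefault(key, []).append(r)
        for key in sorted(groups):
            _assign(groups[key])
    else:
        _assign(list(records))
    return SplitAssignment(assignment=assignment, seed=seed)


def sanitize_records(
    records: list[DomainRecord], policy: str = "unknown"
) -> list[DomainRecord]:
    """Handle noncanonical residues (X, B, Z, U, O).

    ``policy="unknown"`` (default) replaces them with ``X``; the tokenizer
    maps ``X`` to the UNK token, which is excluded from every loss.
    ``policy="reject"`` raises on any record containing one.
    """
    if policy not in ("unknown", "reject"):
        raise ConfigError(f"unknown noncanonical policy {policy!r}")
    canonical = set(AMINO_ACIDS)
    out = []
    for r in records:
        bad = [c for c in r.sequence if c not in canonical]
        if bad:
            unknown_bad = set(bad) - set(NONCANONICAL)
            if unknown_bad:
                raise AnnotationError(
                    f"record {r.id!r}: characters {sorted(unknown_bad)} are not "
                    "amino acids or recognised noncanonical codes"
                )
            if policy == "reject":
                raise AnnotationError(
                    f"record {r.id!r} contains noncanonical residues {sorted(set(bad))}"
                )
            seq = "".join(c if c in canonical else "X" for c in r.sequence)
            r = replace(r, sequence=seq)
        out.append(r)
    return out
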