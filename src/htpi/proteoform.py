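"""Proteoform data model, naming grammar and truncation/PTM-aware mass calculus.

A *proteoform* here is a gene product defined by an inclusive 1-based residue
range of the unprocessed database sequence plus a multiset of whole-molecule
post-translational modifications.  Names follow the convention used for
intact-mass imaging work, e.g. ``Pcp4(2–62)@Ac@Phospho``: gene symbol,
residue range (en-dash or hyphen on input, en-dash on output), then one
``@Code`` suffix per modification occurrence.

Masses are computed in both monoisotopic and average flavours.  Linear-TOF
MALDI peaks of 3–20 kDa proteins are unresolved isotope envelopes whose
apex sits at the *average* mass, while top-down identifications carry
*monoisotopic* neutral masses; at 10 kDa the two differ by ~6 Da (~0.06%),
which exceeds the ±0.05% matching tolerance, so keeping both and matching
in average-mass space is essential (see :mod:`htpi.annotate`).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from pyteomics import mass as _pmass

__all__ = [
    "ModificationSpec",
    "ProteoformRecord",
    "ProteoformError",
    "ProteoformParseError",
    "ResidueRangeError",
    "UnknownGeneError",
    "SequenceError",
    "UnknownModificationError",
    "MOD_REGISTRY",
    "register_modification",
    "compute_masses",
    "mono_to_avg_estimate",
    "parse_proteoform_name",
    "format_proteoform_name",
    "read_id_table",
    "write_id_table",
]

EN_DASH = "–"

WATER_MONO = 18.01056
WATER_AVG = 18.0153
PROTON = 1.00728

#: Senko averagine building block (C4.9384 H7.7583 N1.3577 O1.4773 S0.0417).
AVERAGINE_MONO = 111.0543
AVERAGINE_AVG = 111.1254
#: average/monoisotopic mass ratio of the averagine unit (~1.00064); used to
#: estimate an average mass for database rows that carry only a monoisotopic
#: mass and no sequence.
AVERAGINE_RATIO = AVERAGINE_AVG / AVERAGINE_MONO

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Residue mass tables are taken from pyteomics' element data once at import;
# the test suite checks them against an independently keyed-in table.
RESIDUE_MONO: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES
}
RESIDUE_AVG: dict[str, float] = {
    aa: _pmass.calculate_mass(parsed_sequence=[aa], average=True)
    for aa in CANONICAL_RESIDUES
}


class ProteoformError(ValueError):
    """Base class for proteoform domain errors."""


class ProteoformParseError(ProteoformError):
    def __init__(self, name: str, position: int, message: str):
        self.name = name
        self.position = position
        super().__init__(f"cannot parse {name!r} at position {position}: {message}")


class ResidueRangeError(ProteoformError):
    pass


class UnknownGeneError(ProteoformError, KeyError):
    pass


class SequenceError(ProteoformError):
    pass


class UnknownModificationError(ProteoformError):
    pass


@dataclass(frozen=True)
class ModificationSpec:
    """One modification class attached to a proteoform.

    Repeated occurrences of the same class are expressed through ``count``,
    never through duplicate entries.  Site positions are not modelled: the
    naming convention carries none.
    """

    code: str
    mono_delta: float
    avg_delta: float
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ProteoformError(f"modification count must be >= 1, got {self.count}")


# Unimod-standard mass shifts for the four modification classes that matter
# for intact brain proteoforms in this mass range (mono, average, in Da).
MOD_REGISTRY: dict[str, tuple[float, float]] = {
    "Ac": (42.01057, 42.0367),
    "Me": (14.01565, 14.0266),
    "Phospho": (79.96633, 79.9799),
    "Oxi": (15.99491, 15.9994),
}


def register_modification(code: str, mono_delta: float, avg_delta: float) -> None:
    """Add a modification class to the registry (idempotent for equal values)."""
    if code in MOD_REGISTRY and MOD_REGISTRY[code] != (mono_delta, avg_delta):
        raise ProteoformError(f"modification {code!r} already registered with different masses")
    MOD_REGISTRY[code] = (mono_delta, avg_delta)


def _mod_from_code(code: str, count: int = 1) -> ModificationSpec:
    try:
        mono, avg = MOD_REGISTRY[code]
    except KeyError:
        raise UnknownModificationError(
            f"unknown modification code {code!r}; registry: {sorted(MOD_REGISTRY)}"
        ) from None
    return ModificationSpec(code, mono, avg, count)


def compute_masses(
    sequence_slice: str, mods: list[ModificationSpec] | tuple[ModificationSpec, ...] = ()
) -> tuple[float, float]:
    """Neutral (monoisotopic, average) mass of a residue slice plus mods.

    ``mono = sum(residue mono) + H2O + sum(mod mono_delta * count)`` and the
    average analogue.  Raises :class:`SequenceError` naming the first
    non-canonical residue.
    """
    if not sequence_slice:
        raise SequenceError("empty sequence slice")
    mono = WATER_MONO
    avg = WATER_AVG
    for i, aa in enumerate(sequence_slice):
        try:
            mono += RESIDUE_MONO[aa]
            avg += RESIDUE_AVG[aa]
        except KeyError:
            raise SequenceError(
                f"non-canonical residue {aa!r} at position {i + 1}"
            ) from None
    for m in mods:
        mono += m.mono_delta * m.count
        avg += m.avg_delta * m.count
    return mono, avg


def mono_to_avg_estimate(mono_mass: float) -> float:
    """Averagine-based estimate of the average mass from a monoisotopic mass.

    Valid for intact proteins in the 1–25 kDa window where the averagine
    elemental composition is a good proxy.
    """
    if not (1000.0 <= mono_mass <= 25000.0):
        raise ProteoformError(
            f"mono mass {mono_mass!r} outside the supported 1000-25000 Da window"
        )
    return mono_mass * AVERAGINE_RATIO


@dataclass(frozen=True)
class ProteoformRecord:
    """One identified proteoform.

    ``start``/``end`` are 1-based inclusive residue coordinates into
    ``full_sequence``.  For mass-only database rows ``full_sequence`` may be
    empty; masses then come from the stored monoisotopic mass and the
    averagine estimate, and ``sequence_exact`` is False.
    """

    gene: str
    full_sequence: str
    start: int
    end: int
    mods: tuple[ModificationSpec, ...] = ()
    mono_mass: float = 0.0
    avg_mass: float = 0.0
    source_region: str = ""

    def __post_init__(self):
        if self.full_sequence:
            n = len(self.full_sequence)
            if not (1 <= self.start <= self.end <= n):
                raise ResidueRangeError(
                    f"{self.gene}: range {self.start}-{self.end} invalid for "
                    f"sequence of length {n}"
                )
        codes = [m.code for m in self.mods]
        if len(codes) != len(set(codes)):
            raise ProteoformError(
                f"{self.gene}: duplicate modification codes {codes}; use count"
            )
        if self.full_sequence:
            mono, avg = compute_masses(self.sequence, self.mods)
            object.__setattr__(self, "mono_mass", mono if self.mono_mass == 0.0 else self.mono_mass)
            object.__setattr__(self, "avg_mass", avg)
        elif self.mono_mass > 0.0 and self.avg_mass == 0.0:
            object.__setattr__(self, "avg_mass", mono_to_avg_estimate(self.mono_mass))

    # -- derived views ----------------------------------------------------
    @property
    def sequence(self) -> str:
        """The residue slice this proteoform covers."""
        return self.full_sequence[self.start - 1 : self.end]

    @property
    def sequence_exact(self) -> bool:
        return bool(self.full_sequence)

    @property
    def display_name(self) -> str:
        return format_proteoform_name(self)

    @property
    def avg_mz(self) -> float:
        """Theoretical average [M+H]+ m/z, the quantity a linear TOF observes."""
        return self.avg_mass + PROTON

    def with_region(self, region: str) -> "ProteoformRecord":
        return replace(self, source_region=region)


_NAME_RE = re.compile(
    r"^(?P<gene>[^()@\s]+)\((?P<start>\d+)[" + EN_DASH + r"-](?P<end>\d+)\)(?P<mods>(?:@[^@()\s]+)*)$"
)


def parse_proteoform_name(
    name: str, sequence_lookup: dict[str, str], source_region: str = ""
) -> ProteoformRecord:
    """Parse ``Gene(start–end)[@Mod]*`` into a fully populated record.

    The dash may be an en-dash or a hyphen.  Masses are recomputed from the
    sequence slice via :func:`compute_masses`.
    """
    m = _NAME_RE.match(name)
    if m is None:
        # locate the first offending character for a useful message
        pos = 0
        for i, ch in enumerate(name):
            if ch in "()@" or ch.isspace():
                pos = i
                break
        raise ProteoformParseError(name, pos, "expected Gene(start–end)[@Mod]*")
    gene = m.group("gene")
    start, end = int(m.group("start")), int(m.group("end"))
    if start > end:
        raise ResidueRangeError(f"{name}: start {start} > end {end}")
    if gene not in sequence_lookup:
        raise UnknownGeneError(f"gene {gene!r} not in sequence lookup")
    seq = sequence_lookup[gene]
    if end > len(seq):
        raise ResidueRangeError(
            f"{name}: end {end} beyond sequence length {len(seq)}"
        )
    counts: dict[str, int] = {}
    mods_str = m.group("mods")
    if mods_str:
        for code in mods_str.split("@")[1:]:
            counts[code] = counts.get(code, 0) + 1
    mods = tuple(_mod_from_code(c, n) for c, n in counts.items())
    return ProteoformRecord(
        gene=gene, full_sequence=seq, start=start, end=end, mods=mods,
        source_region=source_region,
    )


def format_proteoform_name(record: ProteoformRecord) -> str:
    """Canonical display name; emits the en-dash and one @Code per occurrence."""
    mods = ""
    for m in record.mods:
        mods += f"@{m.code}" * m.count
    return f"{record.gene}({record.start}{EN_DASH}{record.end}){mods}"


# -- ID table I/O ---------------------------------------------------------
# Tab-separated, UTF-8, one header row.  ``mods`` is semicolon-joined
# ``code×count``; ``mono_mass`` may be blank when a sequence is present.

ID_TABLE_COLUMNS = [
    "display_name", "gene", "full_sequence", "start", "end", "mods",
    "mono_mass", "source_region",
]


def _mods_to_str(mods: tuple[ModificationSpec, ...]) -> str:
    return ";".join(f"{m.code}×{m.count}" for m in mods)


def _mods_from_str(s: str) -> tuple[ModificationSpec, ...]:
    s = s.strip()
    if not s:
        return ()
    out = []
    for part in s.split(";"):
        code, _, n = part.replace("x", "×").partition("×")
        out.append(_mod_from_code(code.strip(), int(n) if n else 1))
    return tuple(out)


def write_id_table(records: list[ProteoformRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ID_TABLE_COLUMNS) + "\n")
        for r in records:
            mono = f"{r.mono_mass:.5f}" if r.mono_mass else ""
            fh.write(
                "\t".join(
                    [
                        r.display_name, r.gene, r.full_sequence,
                        str(r.start), str(r.end), _mods_to_str(r.mods),
                        mono, r.source_region,
                    ]
                )
                + "\n"
            )


def read_id_table(path) -> list[ProteoformRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        missing = set(ID_TABLE_COLUMNS) - set(idx)
        if missing:
            raise ProteoformError(f"ID table {path}: missing columns {sorted(missing)}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            mono = f[idx["mono_mass"]].strip()
            records.append(
                ProteoformRecord(
                    gene=f[idx["gene"]],
                    full_sequence=f[idx["full_sequence"]].strip(),
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    mods=_mods_from_str(f[idx["mods"]]),
                    mono_mass=float(mono) if mono else 0.0,
                    source_region=f[idx["source_region"]].strip(),
                )
            )
    return records
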