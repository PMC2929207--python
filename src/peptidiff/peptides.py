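"""Theoretical peptide masses, in-silico tryptic digestion and ppm matching.

This module bridges the quantitative MALDI peak masses (assumed singly
protonated, [M+H]+) and peptide identity: it computes theoretical
monoisotopic masses for (modified) peptide sequences, digests protein
sequences in silico with trypsin, and annotates observed m/z values by
parts-per-million matching against a candidate list.

Modification conventions
------------------------
Cysteine carboxymethylation (+57.021 u) is treated as a fixed modification
applied to every Cys; methionine oxidation (+15.996 u) is variable and is
generated for every combination of Met sites when digesting.  The deltas
default to these three-decimal values so that 2 ppm matching behaves the
same way as the original analysis; full-precision values are available as
``CARBOXYMETHYL_CYS_EXACT`` and ``MET_OXIDATION_EXACT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .errors import ConfigurationError

# Monoisotopic residue masses (u) for the 20 standard amino acids.
RESIDUE_MONO = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER = 18.0105646863
PROTON = 1.00727646688

#: Fixed Cys carboxymethylation delta, at the precision used throughout.
CARBOXYMETHYL_CYS = 57.021
#: Variable Met oxidation delta.
MET_OXIDATION = 15.996
#: Full-precision alternatives.
CARBOXYMETHYL_CYS_EXACT = 57.021464
MET_OXIDATION_EXACT = 15.994915


def mono_mass(sequence: str, modifications: Iterable[tuple[int, float]] = ()) -> float:
    """Neutral monoisotopic mass of a peptide in u.

    Parameters
    ----------
    sequence : str
        Peptide sequence over the 20-letter amino-acid alphabet.
    modifications : iterable of (position, delta)
        0-based residue positions and mass deltas in u to add.

    Returns
    -------
    float
        Sum of residue monoisotopic masses, one water, and all deltas.

    Raises
    ------
    ConfigurationError
        If the sequence is empty, contains an invalid residue (the message
        names the position), or a modification position is out of range.
    """
    if not sequence:
        raise ConfigurationError("sequence: must be non-empty")
    total = WATER
    for i, aa in enumerate(sequence):
        try:
            total += RESIDUE_MONO[aa]
        except KeyError:
            raise ConfigurationError(
                f"sequence: invalid residue {aa!r} at position {i}"
            ) from None
    for pos, delta in modifications:
        if not 0 <= pos < len(sequence):
            raise ConfigurationError(
                f"modifications: position {pos} out of range for length {len(sequence)}"
            )
        total += delta
    return total


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide with modifications and its theoretical masses.

    ``modifications`` holds (0-based position, delta in u) pairs; every Cys
    carries the fixed carboxymethyl delta, Met oxidation appears only where
    applied.  ``mz_1plus`` is the singly protonated [M+H]+ m/z.
    """

    sequence: str
    modifications: tuple[tuple[int, float], ...] = ()
    source_protein: str = ""
    missed_cleavages: int = 0
    neutral_mono_mass: float = field(init=False, default=0.0)
    mz_1plus: float = field(init=False, default=0.0)

    def __post_init__(self):
        mass = mono_mass(self.sequence, self.modifications)
        object.__setattr__(self, "neutral_mono_mass", mass)
        object.__setattr__(self, "mz_1plus", mass + PROTON)


def make_peptide(
    sequence: str,
    *,
    oxidized_met: Sequence[int] = (),
    fixed_cys_delta: float = CARBOXYMETHYL_CYS,
    met_oxidation_delta: float = MET_OXIDATION,
    source_protein: str = "",
    missed_cleavages: int = 0,
) -> PeptideRecord:
    """Build a :class:`PeptideRecord` applying the fixed-Cys convention.

    ``oxidized_met`` lists 0-based positions of oxidized methionines; each
    must actually be an M.
    """
    mods: list[tuple[int, float]] = []
    for i, aa in enumerate(sequence):
        if aa == "C":
            mods.append((i, fixed_cys_delta))
    for pos in oxidized_met:
        if not (0 <= pos < len(sequence)) or sequence[pos] != "M":
            raise ConfigurationError(
                f"oxidized_met: position {pos} is not a methionine in {sequence!r}"
            )
        mods.append((pos, met_oxidation_delta))
    return PeptideRecord(
        sequence=sequence,
        modifications=tuple(sorted(mods)),
        source_protein=source_protein,
        missed_cleavages=missed_cleavages,
    )


def parse_peptide_notation(notation: str) -> tuple[str, tuple[int, ...]]:
    """Parse ``"SALM*PAQLFFK"``-style notation into (sequence, oxidized Met positions).

    An asterisk marks oxidation of the preceding methionine.
    """
    sequence: list[str] = []
    oxidized: list[int] = []
    for ch in notation:
        if ch == "*":
            if not sequence or sequence[-1] != "M":
                raise ConfigurationError(
                    f"notation: '*' not preceded by M in {notation!r}"
                )
            oxidized.append(len(sequence) - 1)
        else:
            sequence.append(ch)
    return "".join(sequence), tuple(oxidized)


def tryptic_cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin cuts: C-terminal to K/R, not before P."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    protein_sequence: str,
    max_missed: int = 2,
    *,
    source_protein: str = "",
    fixed_cys_delta: float = CARBOXYMETHYL_CYS,
    met_oxidation_delta: float = MET_OXIDATION,
    variable_met_oxidation: bool = True,
    min_length: int = 1,
) -> list[PeptideRecord]:
    """In-silico tryptic digest with up to ``max_missed`` missed cleavages.

    Cleaves C-terminal to K and R except when the next residue is proline
    (Keil rule).  Each record is labelled with its missed-cleavage count.
    When ``variable_met_oxidation`` is true, every combination of oxidized
    methionines is emitted as a separate record.
    """
    if max_missed < 0:
        raise ConfigurationError("max_missed: must be non-negative")
    sites = tryptic_cleavage_sites(protein_sequence)
    bounds = [0] + sites + [len(protein_sequence)]
    records: list[PeptideRecord] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for missed in range(max_missed + 1):
            j = i + missed + 1
            if j > n_frag:
                break
            pep = protein_sequence[bounds[i] : bounds[j]]
            if len(pep) < min_length:
                continue
            met_sites = [k for k, aa in enumerate(pep) if aa == "M"]
            variants: list[tuple[int, ...]] = [()]
            if variable_met_oxidation and met_sites:
                for r in range(1, len(met_sites) + 1):
                    variants.extend(combinations(met_sites, r))
            for ox in variants:
                records.append(
                    make_peptide(
                        pep,
                        oxidized_met=ox,
                        fixed_cys_delta=fixed_cys_delta,
                        met_oxidation_delta=met_oxidation_delta,
                        source_protein=source_protein,
                        missed_cleavages=missed,
                    )
                )
    return records


@dataclass(frozen=True)
class MassMatch:
    """One observed m/z matched to one candidate peptide within the cutoff."""

    observed_mz: float
    peptide: PeptideRecord
    error_ppm: float


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    return 1e6 * (observed - theoretical) / theoretical


def match_masses(
    observed_mzs: Sequence[float],
    candidates: Sequence[PeptideRecord],
    cutoff_ppm: float = 2.0,
) -> list[MassMatch]:
    """All (observed, candidate) pairs with |ppm error| <= ``cutoff_ppm``.

    Matches are against the singly protonated candidate mass and are sorted
    by absolute ppm error.  One observed m/z may match several peptides;
    ambiguity is preserved.
    """
    matches: list[MassMatch] = []
    for obs in observed_mzs:
        for pep in candidates:
            err = ppm_error(obs, pep.mz_1plus)
            if abs(err) <= cutoff_ppm:
                matches.append(MassMatch(obs, pep, err))
    matches.sort(key=lambda m: abs(m.error_ppm))
    return matches


# Abundant tryptic peptides of human serum albumin, free of Cys and Met so
# their masses do not depend on the modification conventions.  These serve
# as the default "omnipresent albumin" internal calibrants.
HSA_CALIBRANT_PEPTIDES = (
    "LVNEVTEFAK",
    "YLYEIAR",
    "AEFAEVSK",
    "QTALVELVK",
    "LVTDLTK",
)


def hsa_reference_mzs() -> list[float]:
    """[M+H]+ m/z of the five default albumin calibrant peptides, ascending."""
    return sorted(mono_mass(p) + PROTON for p in HSA_CALIBRANT_PEPTIDES)


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences from FASTA as accession -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def digest_fasta(path, max_missed: int = 2, **kwargs) -> list[PeptideRecord]:
    """Tryptic digest of every protein in a FASTA file."""
    records: list[PeptideRecord] = []
    for acc, seq in read_fasta(path).items():
        records.extend(
            tryptic_digest(seq, max_missed=max_missed, source_protein=acc, **kwargs)
        )
    return records
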