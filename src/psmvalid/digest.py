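"""In-silico tryptic digestion and the observable-peptide index.

The database digest defines what the instrument could in principle have
seen: every fully tryptic peptide whose mass, in at least one searched
modification state, falls inside the acquisition mass window.  The counts
it yields — ``n`` observable peptides per protein and ``D`` over the whole
database — are the denominators of the protein hit count (PHC) feature, and
the per-protein residue spans feed the potential coverage ratio (PCR).

Trypsin cleaves C-terminal of K or R except when the next residue is
proline; protein termini always count as valid tryptic boundaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from pyteomics import mass as _pt_mass

from .io_formats import AMINO_ACIDS, PROTON_MASS, ProteinRecord

#: Monoisotopic residue masses (Da), 20 canonical letters.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pt_mass.std_aa_mass[aa] for aa in sorted(AMINO_ACIDS)
}
#: Monoisotopic mass of water (Da), added once per peptide.
WATER_MASS = 18.0105646863


@dataclass(frozen=True)
class Ptm:
    """A searched post-translational modification.

    residues: target residue letters (e.g. "STY"); delta_mass in Da;
    max_per_peptide caps how many copies one peptide may carry.
    """
    residues: str
    delta_mass: float
    name: str = ""
    max_per_peptide: int = 3


#: The modifications searched for the reference data: methylation,
#: oxidation and phosphorylation.
DEFAULT_PTMS = (
    Ptm("M", 15.994915, "oxidation"),
    Ptm("KR", 14.015650, "methylation"),
    Ptm("STY", 79.966331, "phosphorylation"),
)


@dataclass(frozen=True)
class DigestParams:
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_mass: float = 600.0     # Da; typical MALDI-TOF/TOF window
    max_mass: float = 4000.0
    searched_ptms: tuple[Ptm, ...] = DEFAULT_PTMS
    #: cap on simultaneous modifications when testing observability
    max_total_mods: int = 3

    def __post_init__(self) -> None:
        if self.min_mass >= self.max_mass:
            raise ValueError("min_mass must be < max_mass")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


@dataclass(frozen=True)
class Peptide:
    sequence: str
    protein_accession: str
    start_pos: int            # 1-based index in the protein
    missed_cleavages: int
    ntt: int                  # tryptic termini, 2 = fully tryptic
    neutral_mass: float       # Da; NaN if the sequence contains X


# Cleavage rules map a sequence to the 0-based indices i such that a cut
# occurs between residue i and i+1.
def _trypsin_sites(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 1)
            if seq[i] in "KR" and seq[i + 1] != "P"]


CLEAVAGE_RULES: dict[str, Callable[[str], list[int]]] = {
    "trypsin": _trypsin_sites,
}


def peptide_mass(sequence: str, modifications: Sequence[float] = ()) -> float:
    """Monoisotopic neutral mass of a peptide plus modification deltas."""
    if not sequence:
        raise ValueError("empty peptide has no defined mass")
    total = WATER_MASS
    for aa in sequence:
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r}") from None
    return total + sum(modifications)


def peptide_mh(sequence: str, modifications: Sequence[float] = ()) -> float:
    """Singly protonated (MH+) mass."""
    return peptide_mass(sequence, modifications) + PROTON_MASS


def digest_protein(protein: ProteinRecord,
                   params: DigestParams = DigestParams()) -> list[Peptide]:
    """Enumerate all fully tryptic peptides with up to the allowed number of
    internal missed cleavage sites.

    A protein without any cleavage site yields itself as a single peptide.
    Peptides containing 'X' get ``neutral_mass = nan``.
    """
    seq = protein.sequence
    if not seq:
        raise ValueError(f"protein {protein.accession!r} has an empty sequence")
    sites = CLEAVAGE_RULES[params.enzyme](seq)
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]

    # prefix sums of residue masses; X counted separately so its undefined
    # mass only poisons the peptides that actually contain it
    res = np.array([RESIDUE_MASSES.get(aa, 0.0) for aa in seq])
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    x_prefix = np.concatenate([[0], np.cumsum([aa == "X" for aa in seq])])

    peptides: list[Peptide] = []
    nseg = len(bounds) - 1
    for a in range(nseg):
        for mc in range(params.max_missed_cleavages + 1):
            b = a + mc + 1
            if b > nseg:
                break
            start, end = bounds[a], bounds[b]
            if x_prefix[end] - x_prefix[start] > 0:
                mass = math.nan
            else:
                mass = prefix[end] - prefix[start] + WATER_MASS
            peptides.append(Peptide(
                sequence=seq[start:end],
                protein_accession=protein.accession,
                start_pos=start + 1,
                missed_cleavages=mc,
                ntt=2,
                neutral_mass=float(mass),
            ))
    return peptides


def count_tryptic_termini(peptide_seq: str, protein: ProteinRecord,
                          start_pos: int) -> int:
    """Count peptide termini consistent with tryptic cleavage (0, 1 or 2).

    N-terminus: tryptic if the peptide starts the protein, or the preceding
    residue is K/R and the peptide's first residue is not P.  C-terminus:
    tryptic if the peptide ends the protein or its last residue is K/R
    (and the following residue is not P).
    """
    seq = protein.sequence
    i = start_pos - 1
    j = i + len(peptide_seq)
    if seq[i:j] != peptide_seq:
        raise ValueError(
            f"peptide {peptide_seq!r} is not a substring of "
            f"{protein.accession!r} at position {start_pos}")
    ntt = 0
    if i == 0 or (seq[i - 1] in "KR" and peptide_seq[0] != "P"):
        ntt += 1
    if j == len(seq) or (peptide_seq[-1] in "KR" and seq[j] != "P"):
        ntt += 1
    return ntt


def _achievable_mod_deltas(sequence: str, params: DigestParams) -> list[float]:
    """Distinct total mass shifts reachable with the searched PTMs.

    Enumerates per-PTM copy counts capped by the number of applicable
    residues, the PTM's own cap, and the global cap on simultaneous
    modifications.  Includes 0.0 (the unmodified state).
    """
    ranges = []
    for ptm in params.searched_ptms:
        applicable = sum(sequence.count(r) for r in ptm.residues)
        ranges.append(range(min(applicable, ptm.max_per_peptide) + 1))
    deltas = set()
    for counts in itertools.product(*ranges):
        if sum(counts) > params.max_total_mods:
            continue
        deltas.add(sum(c * p.delta_mass
                       for c, p in zip(counts, params.searched_ptms)))
    return sorted(deltas) if deltas else [0.0]


@dataclass
class DigestIndex:
    """Observable-peptide index over a whole database.

    observable maps accession -> set of observable peptide sequences;
    ``n_per_protein`` and ``total_d`` are the PHC denominators n and D.
    The same sequence occurring in two proteins counts toward both (each
    Sequest hit is linkable to one specific parent protein).
    """
    observable: dict[str, set[str]]
    n_per_protein: dict[str, int]
    total_d: int
    params: DigestParams
    protein_length: dict[str, int]
    #: accession -> {sequence -> [(start0, end0), ...]} occurrence spans
    positions: dict[str, dict[str, list[tuple[int, int]]]]
    #: accession -> {sequence -> unmodified neutral mass}
    masses: dict[str, dict[str, float]]
    _sorted_masses: np.ndarray | None = field(default=None, repr=False)

    @property
    def sorted_masses(self) -> np.ndarray:
        """All observable peptide masses (per-protein duplicates included),
        sorted ascending; used for mass-window counting."""
        if self._sorted_masses is None:
            vals = [m for d in self.masses.values() for m in d.values()]
            self._sorted_masses = np.sort(np.asarray(vals))
        return self._sorted_masses

    def count_in_mass_window(self, neutral_mass: float, window: float) -> int:
        arr = self.sorted_masses
        lo = np.searchsorted(arr, neutral_mass - window, side="left")
        hi = np.searchsorted(arr, neutral_mass + window, side="right")
        return int(hi - lo)


def build_digest_index(database: Iterable[ProteinRecord],
                       params: DigestParams = DigestParams()) -> DigestIndex:
    """Digest every protein and keep the observable peptides.

    A peptide is observable if its unmodified mass, or its mass in some
    admissible combination of searched PTMs, lies within the instrument
    window.  Peptides containing 'X' are excluded (mass undefined).
    """
    database = list(database)
    if not database:
        raise ValueError("empty database")
    observable: dict[str, set[str]] = {}
    positions: dict[str, dict[str, list[tuple[int, int]]]] = {}
    masses: dict[str, dict[str, float]] = {}
    lengths: dict[str, int] = {}
    lo, hi = params.min_mass, params.max_mass

    for protein in database:
        acc = protein.accession
        lengths[acc] = len(protein.sequence)
        obs: set[str] = set()
        pos: dict[str, list[tuple[int, int]]] = {}
        pmass: dict[str, float] = {}
        for pep in digest_protein(protein, params):
            if math.isnan(pep.neutral_mass):
                continue  # contains X
            seq = pep.sequence
            if seq not in obs:
                if lo <= pep.neutral_mass <= hi:
                    ok = True
                else:
                    ok = any(lo <= pep.neutral_mass + d <= hi
                             for d in _achievable_mod_deltas(seq, params))
                if not ok:
                    continue
                obs.add(seq)
                pmass[seq] = pep.neutral_mass
                pos[seq] = []
            span = (pep.start_pos - 1, pep.start_pos - 1 + len(seq))
            if span not in pos[seq]:
                pos[seq].append(span)
        observable[acc] = obs
        positions[acc] = pos
        masses[acc] = pmass

    n_per = {acc: len(s) for acc, s in observable.items()}
    return DigestIndex(
        observable=observable, n_per_protein=n_per,
        total_d=sum(n_per.values()), params=params,
        protein_length=lengths, positions=positions, masses=masses,
    )
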