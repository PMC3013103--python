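"""Readers and writers for the external formats of the pipeline.

Canonical inputs are a FASTA protein database, MGF peak lists and a
documented tab-separated PSM dialect carrying Sequest-style scores for the
ten top-ranked candidate peptides of every searched spectrum.  A tolerant
pepXML reader is provided as a convenience for data exported from other
pipelines.  All masses are monoisotopic; precursor masses are kept on the
singly-protonated (MH+) scale throughout.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _mgf

#: Mass of a proton on the MH+ scale, Da.
PROTON_MASS = 1.00728

#: The 20 canonical amino-acid letters.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: FASTA additionally admits 'X' (unknown residue; mass undefined).
FASTA_ALPHABET = AMINO_ACIDS | {"X"}

#: Column order of the PSM TSV dialect.
PSM_COLUMNS = (
    "spectrum_id", "rank", "peptide", "modifications", "protein",
    "xcorr", "deltacn", "sp", "sprank", "matched_ions", "total_ions", "label",
)

MAX_RANK = 10


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str


@dataclass(frozen=True)
class Modification:
    """A residue modification: 1-based position and mass shift in Da."""
    position: int
    delta_mass: float
    name: str = ""


@dataclass
class SpectrumRecord:
    spectrum_id: str
    precursor_mh: float  # singly-protonated parent mass, Da
    charge: int
    peaks: np.ndarray    # (n, 2) array of (mz, intensity), sorted by mz

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class PsmCandidate:
    """One ranked peptide match for one spectrum (a classification instance)."""
    spectrum_id: str
    rank: int
    peptide_sequence: str
    modifications: tuple[Modification, ...]
    protein_accession: str
    xcorr: float
    delta_cn: float
    sp: float
    sp_rank: int
    matched_ions: int
    total_ions: int
    label: int | None = None


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA protein database.

    Sequences are uppercased and validated against the 20 canonical residues
    plus 'X'.  Raises ``ValueError`` on an empty file, a file that does not
    start with a '>' header, an invalid residue, or a duplicate accession.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"no records in FASTA file {path}")
    if not lines[0].lstrip().startswith(">"):
        raise ValueError(f"{path}: first non-blank line is not a '>' header")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        bad = set(seq) - FASTA_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains invalid residues {sorted(bad)}")
        if rec.id in seen:
            raise ValueError(f"duplicate accession {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, rec.description, seq))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.description if rec.description else rec.accession
            if not desc.startswith(rec.accession):
                desc = f"{rec.accession} {desc}"
            fh.write(f">{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# MGF

def precursor_mh(pepmass_mz: float, charge: int) -> float:
    """MH+ parent mass from the reported precursor m/z and charge."""
    return charge * pepmass_mz - (charge - 1) * PROTON_MASS


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF peak-list file into :class:`SpectrumRecord` objects.

    TITLE is used as the spectrum id.  A missing CHARGE defaults to 1+
    (MALDI precursors are predominantly singly charged); PEPMASS is
    mandatory.  Peaks are returned sorted ascending by m/z.
    """
    spectra: list[SpectrumRecord] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"{path}: spectrum #{i + 1} has no PEPMASS")
            mz = float(params["pepmass"][0])
            charge_param = params.get("charge")
            charge = int(charge_param[0]) if charge_param else 1
            title = str(params.get("title", f"spectrum_{i + 1}"))
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            order = np.argsort(peaks[:, 0], kind="stable")
            spectra.append(SpectrumRecord(
                spectrum_id=title,
                precursor_mh=precursor_mh(mz, charge),
                charge=charge,
                peaks=peaks[order],
            ))
    return spectra


def write_mgf(spectra: Iterable[SpectrumRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in spectra:
            mz = (sp.precursor_mh + (sp.charge - 1) * PROTON_MASS) / sp.charge
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.spectrum_id}\n")
            fh.write(f"PEPMASS={mz!r}\n")
            fh.write(f"CHARGE={sp.charge}+\n")
            for m, inten in sp.peaks:
                fh.write(f"{float(m)!r} {float(inten)!r}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# PSM TSV dialect

def _format_mods(mods: Sequence[Modification]) -> str:
    return ";".join(f"{m.position}:{m.delta_mass!r}" for m in mods)


def _parse_mods(text: str) -> tuple[Modification, ...]:
    if not text or not str(text).strip():
        return ()
    out = []
    for token in str(text).split(";"):
        pos, _, delta = token.partition(":")
        out.append(Modification(int(pos), float(delta)))
    return tuple(out)


def read_psm_table(path: str | Path) -> list[PsmCandidate]:
    """Read the documented PSM TSV dialect.

    Rows are grouped by spectrum id (grouping is key-based, so interleaved
    rows are fine); within each spectrum ranks must be 1..m with no gaps and
    m <= 10.  The Sequest convention that the rank-1 candidate has
    deltaCn = 0 is checked with a warning, not an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"spectrum_id": str},
                     keep_default_na=True)
    missing = [c for c in PSM_COLUMNS if c not in df.columns and c != "label"]
    if missing:
        raise ValueError(f"{path}: missing PSM columns {missing}")
    if "label" not in df.columns:
        df["label"] = np.nan

    dup = df.duplicated(subset=["spectrum_id", "rank"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["spectrum_id", "rank"]].tolist()
        raise ValueError(f"{path}: duplicate (spectrum_id, rank) {key}")
    if (df["rank"] > MAX_RANK).any():
        raise ValueError(
            f"{path}: rank > {MAX_RANK} found; the dialect carries at most the "
            f"{MAX_RANK} top-ranked tentative peptide matches per spectrum")

    candidates: list[PsmCandidate] = []
    for sid, grp in df.groupby("spectrum_id", sort=True):
        ranks = sorted(grp["rank"].tolist())
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"{path}: spectrum {sid!r} ranks {ranks} are not 1..m")
        grp = grp.sort_values("rank")
        for row in grp.itertuples(index=False):
            if row.rank == 1 and row.deltacn != 0:
                warnings.warn(
                    f"spectrum {sid!r}: rank-1 deltaCn is {row.deltacn}, "
                    "expected 0 by Sequest convention")
            label = None if pd.isna(row.label) else int(row.label)
            mi, ti = int(row.matched_ions), int(row.total_ions)
            if mi > ti:
                raise ValueError(
                    f"{path}: spectrum {sid!r} rank {row.rank}: "
                    f"matched_ions {mi} > total_ions {ti}")
            candidates.append(PsmCandidate(
                spectrum_id=str(sid), rank=int(row.rank),
                peptide_sequence=str(row.peptide),
                modifications=_parse_mods(row.modifications if isinstance(row.modifications, str) else ""),
                protein_accession=str(row.protein),
                xcorr=float(row.xcorr), delta_cn=float(row.deltacn),
                sp=float(row.sp), sp_rank=int(row.sprank),
                matched_ions=mi, total_ions=ti, label=label,
            ))
    return candidates


def psm_frame(candidates: Iterable[PsmCandidate]) -> pd.DataFrame:
    """Flatten candidates into a DataFrame in the dialect's column order."""
    rows = [{
        "spectrum_id": c.spectrum_id, "rank": c.rank,
        "peptide": c.peptide_sequence,
        "modifications": _format_mods(c.modifications),
        "protein": c.protein_accession,
        "xcorr": c.xcorr, "deltacn": c.delta_cn, "sp": c.sp,
        "sprank": c.sp_rank, "matched_ions": c.matched_ions,
        "total_ions": c.total_ions,
        "label": "" if c.label is None else c.label,
    } for c in candidates]
    return pd.DataFrame(rows, columns=list(PSM_COLUMNS))


def write_psm_table(candidates: Iterable[PsmCandidate], path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write candidates in the TSV dialect; round-trips bit-exactly."""
    df = psm_frame(candidates)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(
                repr(v) if isinstance(v, float) else str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# pepXML (optional convenience)

def read_pepxml(path: str | Path) -> list[PsmCandidate]:
    """Tolerant pepXML reader mapping search hits onto :class:`PsmCandidate`.

    Reads xcorr, deltacn, sp(score), sprank and the matched/total ion counts
    from each search hit; hits without these Sequest scores are skipped.
    """
    from pyteomics import pepxml as _pepxml

    candidates: list[PsmCandidate] = []
    with _pepxml.read(str(path)) as reader:
        for query in reader:
            sid = str(query.get("spectrum", query.get("start_scan", "")))
            for hit in query.get("search_hit", []):
                scores = hit.get("search_score", {})
                try:
                    xcorr = float(scores["xcorr"])
                    deltacn = float(scores["deltacn"])
                    sp = float(scores.get("spscore", scores.get("sp", 0.0)))
                    sprank = int(scores.get("sprank", 1))
                except (KeyError, TypeError, ValueError):
                    continue
                proteins = hit.get("proteins") or [{}]
                mods = tuple(
                    Modification(int(m["position"]), float(m.get("mass", 0.0)))
                    for m in hit.get("modifications", []))
                candidates.append(PsmCandidate(
                    spectrum_id=sid, rank=int(hit.get("hit_rank", 1)),
                    peptide_sequence=str(hit["peptide"]),
                    modifications=mods,
                    protein_accession=str(proteins[0].get("protein", "")),
                    xcorr=xcorr, delta_cn=deltacn, sp=sp, sp_rank=sprank,
                    matched_ions=int(hit.get("num_matched_ions", 0)),
                    total_ions=int(hit.get("tot_num_ions", 1)),
                ))
    return candidates
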