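"""Feature calculation for peptide-spectrum match instances.

Every PSM instance is represented by a fixed-order numeric vector with
three groups:

* **Sequest** pass-throughs: xcorr, deltaMH, deltaCn, Sp, SpRank and the
  matched-ion fraction.
* **Published** sequence/spectrum descriptors: tryptic-terminus count,
  peptide length, summed peak intensity, mobile-proton factor, C-terminal
  residue code (Arg=1, Lys=2, other=3), the number of database peptides
  within a mass window of the match, and proline/arginine tallies.
* **Novel** dataset-level evidence: spectral-quality statistics
  (mean/std/count and the 20%-bin intensity histogram), the protein hit
  count (PHC), the potential coverage ratio (PCR) and the PTM percentage.

PHC is the negative-log tail probability of seeing the observed number of
hits for a parent protein under random sampling of the observable-peptide
database: with ``D`` observable peptides database-wide, ``n`` from the
protein and ``P`` sampled instances, the hit count is approximately
Poisson with rate ``lambda = P * n / D``.  The default (and the direction
the learned trees use) is the upper tail, ``-log10 P(X >= k)``, so a large
PHC means more hits than chance predicts; a ``lower`` mode preserving the
literal k-or-fewer formulation is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .digest import DigestIndex, Ptm, peptide_mass
from .io_formats import PROTON_MASS, ProteinRecord, PsmCandidate, SpectrumRecord

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

#: Documented feature order of the matrix (label column, when present, last).
FEATURE_NAMES = (
    # Sequest
    "xcorr", "delta_mh", "delta_cn", "sp", "sp_rank", "ion_fraction",
    # Published
    "ntt", "peptide_length", "summed_intensity", "mpf", "c_terminal_code",
    "mass_window_peptides", "proline_count", "arginine_count",
    # Novel
    "intensity_mean", "intensity_std", "peak_count",
    "intensity_bin1", "intensity_bin2", "intensity_bin3",
    "intensity_bin4", "intensity_bin5",
    "phc", "pcr", "ptm_percentage",
)

#: The dataset-level protein evidence features (the ablation switch target).
PROTEIN_EVIDENCE_FEATURES = ("phc", "pcr")


# ---------------------------------------------------------------------------
# Protein hit count

def phc(k: int, n: int, d: int, p: int, tail: str = "upper") -> float:
    """Protein hit count: -log10 Poisson tail probability of ``k`` hits.

    Parameters are the observed hit count ``k`` for the parent protein, its
    observable-peptide count ``n``, the database observable count ``d`` and
    the number of sampled instances ``p``.  ``tail='upper'`` (default)
    scores P(X >= k); ``tail='lower'`` scores the literal k-or-fewer
    probability P(X <= k).  Computed in log space throughout.
    """
    if p <= 0 or d <= 0:
        raise ValueError("PHC requires P > 0 and D > 0")
    if not 0 <= k <= p:
        raise ValueError(f"k={k} outside [0, P={p}]")
    if not 0 <= n <= d:
        raise ValueError(f"n={n} outside [0, D={d}]")
    if n == 0:
        if k > 0:
            raise ValueError("hits from a protein with no observable peptides")
        return 0.0
    lam = p * (n / d)
    if tail == "upper":
        if k == 0:
            return 0.0  # P(X >= 0) = 1
        log_tail = stats.poisson.logsf(k - 1, lam)
    elif tail == "lower":
        log_tail = stats.poisson.logcdf(k, lam)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(-log_tail / LN10)


# ---------------------------------------------------------------------------
# Potential coverage ratio

def pcr(protein_accession: str, matched_peptides: Iterable[str],
        index: DigestIndex) -> float:
    """Fraction of a protein's observable residues covered by matches.

    Both numerator and denominator are residue unions on protein
    coordinates, so overlapping peptides are not double counted.  Matched
    peptides absent from the observable set (semi-tryptic or out-of-window
    matches) are excluded from the numerator with a logged warning.
    """
    if protein_accession not in index.observable:
        raise KeyError(f"unknown protein {protein_accession!r}")
    spans = index.positions[protein_accession]
    length = index.protein_length[protein_accession]
    all_cov = np.zeros(length, dtype=bool)
    hit_cov = np.zeros(length, dtype=bool)
    matched = set(matched_peptides)
    for seq, occ in spans.items():
        for a, b in occ:
            all_cov[a:b] = True
            if seq in matched:
                hit_cov[a:b] = True
    unknown = matched - set(spans)
    for seq in sorted(unknown):
        logger.warning(
            "peptide %r matched to %s is not in its observable set; "
            "excluded from PCR", seq, protein_accession)
    denom = int(all_cov.sum())
    if denom == 0:
        return 0.0
    return float(hit_cov.sum() / denom)


# ---------------------------------------------------------------------------
# PTM percentage

def ptm_percentage(candidate: PsmCandidate,
                   searched_ptms: Sequence[Ptm]) -> float:
    """Percentage of a peptide's modifiable residues actually modified.

    100 * (modified residues) / (residues that are targets of any searched
    PTM); 0 when the peptide has no modifiable residue.  A modification on
    a non-target residue indicates inconsistent search output and raises.
    """
    targets = set("".join(p.residues for p in searched_ptms))
    seq = candidate.peptide_sequence
    n_targets = sum(1 for aa in seq if aa in targets)
    modified_positions = set()
    for mod in candidate.modifications:
        if not 1 <= mod.position <= len(seq):
            raise ValueError(
                f"modification position {mod.position} outside peptide {seq!r}")
        if seq[mod.position - 1] not in targets:
            raise ValueError(
                f"modification at {seq[mod.position - 1]}{mod.position} in "
                f"{seq!r} is not a target of any searched PTM")
        modified_positions.add(mod.position)
    if n_targets == 0:
        return 0.0
    return 100.0 * len(modified_positions) / n_targets


# ---------------------------------------------------------------------------
# Spectral quality

def spectral_quality_features(spectrum: SpectrumRecord) -> dict[str, float]:
    """Summed/mean/std intensity, peak count and the 20%-bin histogram.

    Intensities are normalized by the per-spectrum maximum; the five bins
    are the fractions of peaks falling in [0,.2), [.2,.4), [.4,.6),
    [.6,.8), [.8,1] and always sum to 1.
    """
    if len(spectrum.peaks) == 0:
        raise ValueError(f"spectrum {spectrum.spectrum_id!r} has no peaks")
    inten = spectrum.peaks[:, 1]
    peak_max = inten.max()
    norm = inten / peak_max if peak_max > 0 else np.ones_like(inten)
    edges = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
    bin_idx = np.minimum(np.searchsorted(edges, norm, side="right") - 1, 4)
    bins = np.bincount(bin_idx, minlength=5) / len(inten)
    out = {
        "summed_intensity": float(inten.sum()),
        "intensity_mean": float(inten.mean()),
        "intensity_std": float(inten.std()),  # population std
        "peak_count": float(len(inten)),
    }
    out.update({f"intensity_bin{i + 1}": float(bins[i]) for i in range(5)})
    return out


# ---------------------------------------------------------------------------
# Published group

def mobile_proton_factor(charge: int, peptide_sequence: str) -> int:
    """Proton-mobility class: 1 mobile, 2 partially mobile, 3 non-mobile.

    Mobile if the precursor charge exceeds the count of basic residues
    (R, K, H); non-mobile if it does not exceed the arginine count.
    """
    n_r = peptide_sequence.count("R")
    n_basic = n_r + peptide_sequence.count("K") + peptide_sequence.count("H")
    if charge <= n_r:
        return 3
    if charge > n_basic:
        return 1
    return 2


def c_terminal_code(peptide_sequence: str) -> int:
    """Arg = 1, Lys = 2, other = 3."""
    last = peptide_sequence[-1]
    return {"R": 1, "K": 2}.get(last, 3)


def published_features(candidate: PsmCandidate, ntt: int,
                       spectrum: SpectrumRecord, index: DigestIndex,
                       mass_window: float = 3.0) -> dict[str, float]:
    seq = candidate.peptide_sequence
    neutral = peptide_mass(seq)
    return {
        "ntt": float(ntt),
        "peptide_length": float(len(seq)),
        "summed_intensity": float(spectrum.peaks[:, 1].sum()),
        "mpf": float(mobile_proton_factor(spectrum.charge, seq)),
        "c_terminal_code": float(c_terminal_code(seq)),
        "mass_window_peptides": float(
            index.count_in_mass_window(neutral, mass_window)),
        "proline_count": float(seq.count("P")),
        "arginine_count": float(seq.count("R")),
    }


# ---------------------------------------------------------------------------
# Sequest group

def sequest_features(candidate: PsmCandidate,
                     spectrum: SpectrumRecord) -> dict[str, float]:
    """Pass-throughs plus deltaMH and the matched-ion fraction.

    deltaMH is the difference between the observed MH+ parent mass and the
    theoretical MH+ mass of the (modified) candidate peptide.  Expert
    cut-offs on these scores are never applied here; they are what the
    classifier learns.
    """
    if candidate.total_ions <= 0:
        raise ValueError(
            f"candidate {candidate.spectrum_id!r} rank {candidate.rank}: "
            "total_ions must be positive")
    theoretical_mh = peptide_mass(
        candidate.peptide_sequence,
        [m.delta_mass for m in candidate.modifications]) + PROTON_MASS
    return {
        "xcorr": float(candidate.xcorr),
        "delta_mh": float(spectrum.precursor_mh - theoretical_mh),
        "delta_cn": float(candidate.delta_cn),
        "sp": float(candidate.sp),
        "sp_rank": float(candidate.sp_rank),
        "ion_fraction": candidate.matched_ions / candidate.total_ions,
    }


# ---------------------------------------------------------------------------
# Matrix assembly

def _best_ntt(peptide: str, protein: ProteinRecord) -> int:
    """Max tryptic-terminus count over all occurrences of the peptide."""
    from .digest import count_tryptic_termini

    best = None
    start = protein.sequence.find(peptide)
    while start != -1:
        ntt = count_tryptic_termini(peptide, protein, start + 1)
        best = ntt if best is None else max(best, ntt)
        if best == 2:
            break
        start = protein.sequence.find(peptide, start + 1)
    if best is None:
        raise ValueError(
            f"peptide {peptide!r} not found in protein {protein.accession!r}")
    return best


def split_spectra(spectrum_ids: Iterable[str], fraction: float = 0.5,
                  seed: int = 0) -> tuple[set[str], set[str]]:
    """Split spectrum ids into two disjoint sets (train fraction first).

    Splitting at spectrum level keeps a spectrum's ranked candidates —
    which share spectral features — on one side of the split.
    """
    ids = sorted(set(spectrum_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_train = int(round(fraction * len(ids)))
    return set(ids[:n_train]), set(ids[n_train:])


def build_feature_matrix(candidates: Sequence[PsmCandidate],
                         spectra: Sequence[SpectrumRecord],
                         database: Sequence[ProteinRecord],
                         index: DigestIndex,
                         mass_window: float = 3.0,
                         phc_tail: str = "upper",
                         k_mode: str = "all_ranks") -> pd.DataFrame:
    """Assemble the full feature matrix for a set of PSM instances.

    Returns a DataFrame indexed by (spectrum_id, rank) with the columns of
    :data:`FEATURE_NAMES` plus a trailing ``label`` column (NaN where the
    label is unknown).  Output is deterministic and invariant to the input
    row order.  PHC and PCR are dataset-global: ``k`` counts the protein's
    PSM instances in *this* dataset (over all ranks by default, rank 1 only
    with ``k_mode='rank1'``) and ``P`` is the instance count.
    """
    candidates = sorted(candidates, key=lambda c: (c.spectrum_id, c.rank))
    spec_by_id = {s.spectrum_id: s for s in spectra}
    prot_by_acc = {p.accession: p for p in database}

    missing_spec = sorted({c.spectrum_id for c in candidates} - set(spec_by_id))
    missing_prot = sorted({c.protein_accession for c in candidates}
                          - set(prot_by_acc))
    if missing_spec or missing_prot:
        raise ValueError(
            f"unresolvable spectra {missing_spec[:5]} / proteins {missing_prot[:5]}")

    p_total = len(candidates)
    if p_total == 0:
        raise ValueError("no candidates to featurize")

    counted = (candidates if k_mode == "all_ranks"
               else [c for c in candidates if c.rank == 1])
    k_counts: dict[str, int] = {}
    matched_by_prot: dict[str, set[str]] = {}
    for c in counted:
        k_counts[c.protein_accession] = k_counts.get(c.protein_accession, 0) + 1
    for c in candidates:
        matched_by_prot.setdefault(c.protein_accession, set()).add(
            c.peptide_sequence)

    phc_cache: dict[str, float] = {}
    pcr_cache: dict[str, float] = {}
    for acc in k_counts:
        n = index.n_per_protein.get(acc, 0)
        phc_cache[acc] = phc(k_counts[acc], n, index.total_d, p_total,
                             tail=phc_tail)
        pcr_cache[acc] = pcr(acc, matched_by_prot[acc], index)

    quality_cache = {sid: spectral_quality_features(spec)
                     for sid, spec in spec_by_id.items()
                     if sid in {c.spectrum_id for c in candidates}}
    ntt_cache: dict[tuple[str, str], int] = {}

    rows = []
    for c in candidates:
        spectrum = spec_by_id[c.spectrum_id]
        protein = prot_by_acc[c.protein_accession]
        key = (c.peptide_sequence, c.protein_accession)
        if key not in ntt_cache:
            ntt_cache[key] = _best_ntt(c.peptide_sequence, protein)
        row: dict[str, float] = {}
        row.update(sequest_features(c, spectrum))
        row.update(published_features(c, ntt_cache[key], spectrum, index,
                                      mass_window))
        row.update(quality_cache[c.spectrum_id])
        row["phc"] = phc_cache.get(c.protein_accession, 0.0)
        row["pcr"] = pcr_cache.get(c.protein_accession, 0.0)
        row["ptm_percentage"] = ptm_percentage(c, index.params.searched_ptms)
        row["label"] = math.nan if c.label is None else float(c.label)
        rows.append(row)

    idx = pd.MultiIndex.from_tuples(
        [(c.spectrum_id, c.rank) for c in candidates],
        names=["spectrum_id", "rank"])
    df = pd.DataFrame(rows, index=idx, columns=list(FEATURE_NAMES) + ["label"])
    bad = df[list(FEATURE_NAMES)].isna()
    if bad.any().any():
        offenders = df.index[bad.any(axis=1)].tolist()[:5]
        raise ValueError(f"undefined feature values for instances {offenders}")
    return df


def write_feature_matrix(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.reset_index().to_csv(fh, sep="\t", index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"spectrum_id": str})
    return df.set_index(["spectrum_id", "rank"])
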