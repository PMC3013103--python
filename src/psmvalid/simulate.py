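"""Synthetic Sequest-like search results for end-to-end testing.

The generator emulates the *structure* of a MALDI reference search — not
MALDI physics: a protein database, a small "present" subset on which true
matches cluster, spectra whose ten top-ranked candidate peptides are
reported, a ~4.7% positive instance fraction, and true matches that rank
first only about two thirds of the time.  Scores for true and decoy
candidates are drawn from overlapping distributions so the classification
problem is hard but learnable; peak lists exist only to exercise the
spectral-quality features.

Scale defaults are roughly a quarter of the reference dataset (which had
~43k instances over ~4.3k spectra and 246 sample proteins searched against
IPI human): 1500 proteins, ~60 present, ~8 true spectra per present
protein, ten candidates per spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .digest import DigestParams, Ptm, digest_protein, build_digest_index, DigestIndex
from .io_formats import (PROTON_MASS, Modification, ProteinRecord,
                         PsmCandidate, SpectrumRecord)

#: residue alphabet and sampling frequencies: K/R tuned so tryptic segments
#: average ~9 residues; P kept low so few cleavages are suppressed.
_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_FREQS = np.full(20, (1.0 - 0.055 * 2 - 0.04) / 17)
_FREQS[_ALPHABET == "K"] = 0.055
_FREQS[_ALPHABET == "R"] = 0.055
_FREQS[_ALPHABET == "P"] = 0.04


@dataclass(frozen=True)
class SimConfig:
    n_proteins: int = 1500
    protein_length: tuple[int, int] = (150, 450)
    present_fraction: float = 0.04
    spectra_per_present_protein: float = 8.0
    candidates_per_spectrum: int = 10
    positive_fraction: float = 0.047   # target positive instance fraction
    cluster_hits: bool = True          # true hits concentrate on present proteins
    seed: int = 0
    digest_params: DigestParams = field(default_factory=DigestParams)
    # score distributions (true strong / true degraded / decoy)
    xcorr_true: tuple[float, float] = (3.0, 0.7)
    xcorr_degraded: tuple[float, float] = (1.7, 0.5)
    xcorr_decoy: tuple[float, float] = (1.5, 0.5)
    strong_true_prob: float = 0.66     # -> ~34% of true matches not ranked first
    ionfrac_true: tuple[float, float] = (9.0, 11.0)   # Beta(a, b)
    ionfrac_degraded: tuple[float, float] = (4.5, 15.5)
    ionfrac_decoy: tuple[float, float] = (3.0, 17.0)
    mod_prob_true: float = 0.05
    mod_prob_decoy: float = 0.35
    precursor_noise_sd: float = 0.02   # Da
    decoy_mass_window: float = 1.5     # Da, candidate mass matching
    decoy_from_database: bool = True
    mean_peaks: float = 30.0
    #: zero-signal null: every candidate is generated through the decoy
    #: path and the positive label is assigned to a random candidate, so
    #: labels carry no feature information at all
    null_features: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.candidates_per_spectrum <= 10:
            raise ValueError("candidates_per_spectrum must be in [1, 10]")
        if not 0.0 < self.present_fraction < 1.0:
            raise ValueError("present_fraction must be in (0, 1)")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")


@dataclass
class SimulatedSearch:
    spectra: list[SpectrumRecord]
    candidates: list[PsmCandidate]
    present_proteins: list[str]
    index: DigestIndex


def _has_observable(protein: ProteinRecord, params: DigestParams) -> bool:
    lo, hi = params.min_mass, params.max_mass
    return any(lo <= p.neutral_mass <= hi
               for p in digest_protein(protein, params)
               if not math.isnan(p.neutral_mass))


def simulate_database(config: SimConfig) -> list[ProteinRecord]:
    """Random protein database; every protein is guaranteed at least one
    observable peptide under the configured digest (rejection sampling).
    Deterministic given the config seed."""
    if config.n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.protein_length
    records: list[ProteinRecord] = []
    for i in range(config.n_proteins):
        for _ in range(100):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(_ALPHABET, size=length, p=_FREQS))
            rec = ProteinRecord(f"SIM{i:05d}", f"SIM{i:05d} synthetic protein", seq)
            if _has_observable(rec, config.digest_params):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not generate an observable protein")
        records.append(rec)
    return records


def _truncated_normal(rng, mean: float, sd: float, low: float = 0.05) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > low:
            return float(v)
    return low


def _apply_mod(rng, seq: str, ptms: Sequence[Ptm]):
    """Pick one applicable searched PTM and a target position; returns
    (modifications tuple, total delta) — empty if nothing applies."""
    applicable = [(ptm, [i + 1 for i, aa in enumerate(seq) if aa in ptm.residues])
                  for ptm in ptms]
    applicable = [(ptm, pos) for ptm, pos in applicable if pos]
    if not applicable:
        return (), 0.0
    ptm, positions = applicable[int(rng.integers(len(applicable)))]
    pos = int(positions[int(rng.integers(len(positions)))])
    return (Modification(pos, ptm.delta_mass, ptm.name),), ptm.delta_mass


class _PeptidePool:
    """All observable peptides of the database, indexed by mass."""

    def __init__(self, index: DigestIndex):
        accs, seqs, masses = [], [], []
        for acc in sorted(index.masses):
            for seq in sorted(index.masses[acc]):
                accs.append(acc)
                seqs.append(seq)
                masses.append(index.masses[acc][seq])
        order = np.argsort(np.asarray(masses), kind="stable")
        self.accessions = np.asarray(accs, dtype=object)[order]
        self.sequences = np.asarray(seqs, dtype=object)[order]
        self.masses = np.asarray(masses)[order]

    def sample_near(self, rng, target_mass: float, window: float,
                    require_residues: str = "") -> int:
        """Index of a random pool peptide with mass within the window,
        widening the window (x2, up to 4 times) and finally falling back to
        the nearest peptide.  If residues are required (to host a searched
        modification) up to 50 window members are probed."""
        w = window
        for _ in range(5):
            lo = np.searchsorted(self.masses, target_mass - w, side="left")
            hi = np.searchsorted(self.masses, target_mass + w, side="right")
            if hi > lo:
                if not require_residues:
                    return int(rng.integers(lo, hi))
                for _ in range(min(50, 3 * (hi - lo))):
                    j = int(rng.integers(lo, hi))
                    if any(r in self.sequences[j] for r in require_residues):
                        return j
            w *= 2
        return int(np.clip(np.searchsorted(self.masses, target_mass),
                           0, len(self.masses) - 1))


def _simulate_peaks(rng, config: SimConfig, precursor_mh: float) -> np.ndarray:
    n = 5 + int(rng.poisson(config.mean_peaks))
    mz = rng.uniform(200.0, max(250.0, precursor_mh), size=n)
    inten = rng.lognormal(mean=6.0, sigma=1.0, size=n)
    peaks = np.column_stack([mz, inten])
    return peaks[np.argsort(peaks[:, 0])]


def simulate_search(database: Sequence[ProteinRecord],
                    config: SimConfig) -> SimulatedSearch:
    """Simulate a labeled ranked-candidate search result over the database.

    Every spectrum reports ``candidates_per_spectrum`` candidates; at most
    one is true.  True spectra are assigned to a small present-protein
    subset (or uniformly, with ``cluster_hits=False``); decoy candidates
    are database peptides mass-matched to the precursor.  Candidate ranks
    follow the simulated XCorr ordering, so the true match lands at rank 1
    whenever its (mixture-drawn) XCorr tops the decoys — about 66% of the
    time at defaults.  deltaCn is computed from the XCorr gaps and is 0 for
    rank 1.
    """
    rng = np.random.default_rng([config.seed, 1])
    index = build_digest_index(database, config.digest_params)
    pool = _PeptidePool(index)
    by_acc = {p.accession: p for p in database}
    ptms = config.digest_params.searched_ptms

    eligible = [acc for acc in sorted(index.observable)
                if index.n_per_protein[acc] > 0]
    n_present = max(1, int(round(config.present_fraction * len(database))))
    if config.cluster_hits:
        present = sorted(rng.choice(np.asarray(eligible, dtype=object),
                                    size=n_present, replace=False).tolist())
        counts = rng.poisson(config.spectra_per_present_protein,
                             size=len(present))
        true_assignment = [acc for acc, c in zip(present, counts)
                           for _ in range(int(c))]
    else:
        n_true = int(rng.poisson(config.spectra_per_present_protein * n_present))
        picks = rng.choice(np.asarray(eligible, dtype=object), size=n_true,
                           replace=True)
        true_assignment = [str(a) for a in picks]
        present = sorted(set(true_assignment))
    if not true_assignment:
        raise ValueError("present-protein subset produced no true spectra")
    rng.shuffle(true_assignment)

    n_true = len(true_assignment)
    per_spec = config.candidates_per_spectrum
    n_total = max(n_true, int(round(n_true / (config.positive_fraction * per_spec))))
    n_decoy_only = n_total - n_true

    spectra: list[SpectrumRecord] = []
    candidates: list[PsmCandidate] = []
    plan = [(True, acc) for acc in true_assignment] + \
           [(False, None)] * n_decoy_only

    for si, (has_true, acc) in enumerate(plan):
        sid = f"S{si + 1:06d}"
        entries = []  # (is_true, seq, acc, mods, delta)
        if has_true and config.null_features:
            # decoy-style spectrum; the label is attached after scoring
            j = int(rng.integers(len(pool.masses)))
            precursor = pool.masses[j] + PROTON_MASS + rng.normal(
                0, config.precursor_noise_sd)
        elif has_true:
            obs = sorted(index.observable[acc])
            seq = obs[int(rng.integers(len(obs)))]
            mods, delta = ((), 0.0)
            if rng.random() < config.mod_prob_true:
                mods, delta = _apply_mod(rng, seq, ptms)
            true_mass = index.masses[acc][seq] + delta
            precursor = true_mass + PROTON_MASS + rng.normal(0, config.precursor_noise_sd)
            entries.append((True, seq, acc, mods, delta))
        else:
            j = int(rng.integers(len(pool.masses)))
            precursor = pool.masses[j] + PROTON_MASS + rng.normal(
                0, config.precursor_noise_sd)

        n_decoys = per_spec - len(entries)
        target_base = precursor - PROTON_MASS
        for _ in range(n_decoys):
            want_mod = rng.random() < config.mod_prob_decoy
            if want_mod:
                ptm = ptms[int(rng.integers(len(ptms)))]
                j = pool.sample_near(rng, target_base - ptm.delta_mass,
                                     config.decoy_mass_window,
                                     require_residues=ptm.residues)
                seq = str(pool.sequences[j])
                if any(r in seq for r in ptm.residues):
                    positions = [i + 1 for i, aa in enumerate(seq)
                                 if aa in ptm.residues]
                    pos = int(positions[int(rng.integers(len(positions)))])
                    mods: tuple[Modification, ...] = (
                        Modification(pos, ptm.delta_mass, ptm.name),)
                    delta = ptm.delta_mass
                else:  # fallback peptide had no target residue
                    mods, delta = (), 0.0
            else:
                j = pool.sample_near(rng, target_base, config.decoy_mass_window)
                seq, mods, delta = str(pool.sequences[j]), (), 0.0
            entries.append((False, seq, str(pool.accessions[j]), mods, delta))

        # scores
        scored = []
        for is_true, seq, pacc, mods, delta in entries:
            if is_true:
                # a ~34% minority of true matches are hard across the board
                # (they are the ones typically not ranked first)
                if rng.random() < config.strong_true_prob:
                    mu, sd = config.xcorr_true
                    fa, fb = config.ionfrac_true
                else:
                    mu, sd = config.xcorr_degraded
                    fa, fb = config.ionfrac_degraded
            else:
                mu, sd = config.xcorr_decoy
                fa, fb = config.ionfrac_decoy
            xcorr = _truncated_normal(rng, mu, sd)
            total_ions = max(4, 2 * (len(seq) - 1))
            frac = rng.beta(fa, fb)
            matched = int(np.clip(round(frac * total_ions), 0, total_ions))
            sp = max(10.0, 200.0 + 180.0 * xcorr + rng.normal(0, 50.0))
            scored.append([is_true, seq, pacc, mods, delta, xcorr, sp,
                           matched, total_ions])

        if has_true and config.null_features:
            scored[int(rng.integers(len(scored)))][0] = True
        scored.sort(key=lambda e: -e[5])
        top_xcorr = scored[0][5]
        sp_order = sorted(range(len(scored)), key=lambda i: -scored[i][6])
        sp_rank = {i: r + 1 for r, i in enumerate(sp_order)}
        for rank0, entry in enumerate(scored):
            is_true, seq, pacc, mods, delta, xcorr, sp, matched, total = entry
            candidates.append(PsmCandidate(
                spectrum_id=sid, rank=rank0 + 1, peptide_sequence=seq,
                modifications=mods, protein_accession=pacc,
                xcorr=round(float(xcorr), 4),
                delta_cn=round(float((top_xcorr - xcorr) / top_xcorr), 4),
                sp=round(float(sp), 2), sp_rank=sp_rank[rank0],
                matched_ions=matched, total_ions=total,
                label=int(is_true),
            ))
        spectra.append(SpectrumRecord(
            spectrum_id=sid,
            precursor_mh=float(precursor),
            charge=1,
            peaks=_simulate_peaks(rng, config, float(precursor)),
        ))

    return SimulatedSearch(spectra=spectra, candidates=candidates,
                           present_proteins=list(present), index=index)


# ---------------------------------------------------------------------------
# End-to-end benchmark

def run_benchmark(seed: int, cluster_hits: bool = True,
                  include_protein_features: bool = True,
                  config: SimConfig | None = None,
                  iterations: int = 9) -> dict:
    """Simulate, split at spectrum level, train, and score held-out AUC.

    The feature matrix is computed separately for each half of the split —
    PHC and PCR are dataset-global, so each dataset must be featurized on
    its own — and the ADTree is trained on one half and evaluated on the
    other.  Returns the held-out AUC plus bookkeeping counts.
    """
    from . import adtree, evaluate
    from .features import (PROTEIN_EVIDENCE_FEATURES, build_feature_matrix,
                           split_spectra)

    if config is None:
        config = SimConfig()
    config = replace(config, seed=seed, cluster_hits=cluster_hits)
    database = simulate_database(config)
    sim = simulate_search(database, config)

    train_ids, test_ids = split_spectra(
        (s.spectrum_id for s in sim.spectra), fraction=0.5, seed=seed)
    spec_by_id = {s.spectrum_id: s for s in sim.spectra}

    def featurize(ids):
        cands = [c for c in sim.candidates if c.spectrum_id in ids]
        specs = [spec_by_id[i] for i in sorted(ids)]
        df = build_feature_matrix(cands, specs, database, sim.index)
        if not include_protein_features:
            df = df.drop(columns=list(PROTEIN_EVIDENCE_FEATURES))
        return df

    train_df, test_df = featurize(train_ids), featurize(test_ids)
    feat_cols = [c for c in train_df.columns if c != "label"]
    model = adtree.train_adtree(
        train_df[feat_cols].to_numpy(), train_df["label"].to_numpy().astype(int),
        feature_names=feat_cols, iterations=iterations, seed=seed)
    margins = model.margins(test_df[feat_cols].to_numpy())
    labels = test_df["label"].to_numpy().astype(int)
    _, auc = evaluate.roc_auc(margins, labels)
    return {
        "auc": auc,
        "n_train": len(train_df), "n_test": len(test_df),
        "positive_fraction": float(
            np.mean([c.label for c in sim.candidates])),
        "model": model, "test_margins": margins, "test_labels": labels,
    }
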