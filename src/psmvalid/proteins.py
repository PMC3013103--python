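"""Protein presence probabilities from calibrated peptide probabilities.

A protein is present if at least one of its matched peptides is a correct
identification.  Treating distinct peptides as independent evidence but
repeated identifications of the same peptide as one observation gives the
conservative noisy-OR estimate

    P(present) = 1 - prod_i (1 - max_j p_ij)

with ``i`` over distinct peptides of the protein and ``j`` over the
identifications of peptide ``i``.  Because every Sequest hit names one
specific parent protein, a peptide shared between two proteins contributes
to both proteins' products.  No parsimony/minimal-set step is applied —
that is a different (EM-based) approach to the inference problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PeptideEvidence:
    peptide_key: str
    best_probability: float
    supporting_instances: tuple[tuple[str, int], ...]  # (spectrum_id, rank)


@dataclass(frozen=True)
class ProteinResult:
    accession: str
    probability: float
    peptide_evidence: tuple[PeptideEvidence, ...]

    @property
    def n_distinct_peptides(self) -> int:
        return len(self.peptide_evidence)

    @property
    def n_psms(self) -> int:
        return sum(len(e.supporting_instances) for e in self.peptide_evidence)


def protein_probability(peptide_probs: Mapping[str, Sequence[float]]) -> float:
    """Noisy-OR over distinct peptides with max within each peptide.

    ``peptide_probs`` maps a distinct-peptide key to the probabilities of
    all its identifications.  Computed in log1p space for stability with
    many peptides.  An empty map raises: a protein with no matched peptide
    has no defined score.
    """
    if not peptide_probs:
        raise ValueError("protein with no matched peptides has no probability")
    log_none = 0.0
    for key, probs in peptide_probs.items():
        if not len(probs):
            raise ValueError(f"peptide {key!r} has no identifications")
        best = max(probs)
        if not 0.0 <= best <= 1.0:
            raise ValueError(f"probability {best} outside [0, 1]")
        if best == 1.0:
            return 1.0
        log_none += math.log1p(-best)
    return float(-math.expm1(log_none))


def rollup(psms: pd.DataFrame, distinct_key: str = "sequence") -> list[ProteinResult]:
    """Aggregate calibrated PSM probabilities into protein results.

    ``psms`` needs columns ``protein``, ``peptide``, ``probability`` and
    the instance key columns ``spectrum_id``, ``rank``; a ``modifications``
    column is required for ``distinct_key='sequence+mods'``.  By default
    modified and unmodified forms of one sequence are the same peptide (the
    non-independence is about repeated sampling of the same molecule).
    Results are sorted by descending probability, ties by accession.
    """
    required = {"protein", "peptide", "probability", "spectrum_id", "rank"}
    missing = required - set(psms.columns)
    if missing:
        raise ValueError(f"rollup input missing columns {sorted(missing)}")
    if distinct_key == "sequence":
        keys = psms["peptide"].astype(str)
    elif distinct_key == "sequence+mods":
        if "modifications" not in psms.columns:
            raise ValueError("distinct_key='sequence+mods' needs a "
                             "modifications column")
        mods = psms["modifications"].fillna("").astype(str)
        keys = psms["peptide"].astype(str) + "|" + mods
    else:
        raise ValueError(f"unknown distinct_key {distinct_key!r}")

    df = psms.assign(_key=keys)
    results = []
    for acc, grp in df.groupby("protein", sort=True):
        evidence = []
        probs: dict[str, list[float]] = {}
        for key, sub in grp.groupby("_key", sort=True):
            plist = sub["probability"].tolist()
            probs[key] = plist
            evidence.append(PeptideEvidence(
                peptide_key=str(key),
                best_probability=float(max(plist)),
                supporting_instances=tuple(
                    (str(r.spectrum_id), int(r.rank))
                    for r in sub.itertuples(index=False)),
            ))
        evidence.sort(key=lambda e: (-e.best_probability, e.peptide_key))
        results.append(ProteinResult(
            accession=str(acc),
            probability=protein_probability(probs),
            peptide_evidence=tuple(evidence),
        ))
    results.sort(key=lambda r: (-r.probability, r.accession))
    return results


def protein_report(results: Iterable[ProteinResult]) -> pd.DataFrame:
    """Flatten results into the report table."""
    rows = []
    for r in results:
        top = r.peptide_evidence[0]
        rows.append({
            "accession": r.accession, "probability": r.probability,
            "n_distinct_peptides": r.n_distinct_peptides, "n_psms": r.n_psms,
            "top_peptide": top.peptide_key,
            "top_probability": top.best_probability,
        })
    return pd.DataFrame(rows, columns=["accession", "probability",
                                       "n_distinct_peptides", "n_psms",
                                       "top_peptide", "top_probability"])
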