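"""Motif co-accessibility: does a candidate motif cooperate with ETS?

ETS-family motifs (ERG, ETS, ETV, FLI — the oncogenic prostate-cancer
family) are first collapsed into a single "ETS" identifier. For each
candidate motif c, peaks are partitioned into BOTH (c and ETS),
C_ONLY (c without ETS) and ETS_ONLY (ETS without c); each partition is
treated as a pseudo-annotation and scored with the chromVAR-style
deviation z per cell. Within a cell subset of interest (the
intermediate population in the motivating analysis), a one-sided
("greater") two-sample rank-sum test asks whether the BOTH z-scores
exceed each exclusive set's z-scores — higher accessibility at
co-occurring sites than at sites with either motif alone. BH adjustment
runs across the candidate motifs tested within the subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atac import ETS_PREFIXES, DeviationResult, MotifAnnotation, compute_deviations
from .matrix import CountMatrix

__all__ = [
    "EtsCollapseRule",
    "PeakPartition",
    "CoAccessResult",
    "collapse_ets",
    "partition_peaks",
    "coaccessibility_test",
    "CooperativityTest",
]


@dataclass(frozen=True)
class EtsCollapseRule:
    """Which gene-symbol prefixes merge into the single ETS identifier."""

    prefixes: tuple[str, ...] = ETS_PREFIXES
    merged: str = "ETS"

    def matches(self, motif: str, genes: Sequence[str]) -> bool:
        names = list(genes) or [motif]
        return any(g.upper().startswith(self.prefixes) for g in names)


def collapse_ets(ann: MotifAnnotation, rule: EtsCollapseRule | None = None) -> MotifAnnotation:
    """Merge all ETS-family motif columns into one union "ETS" column.

    Family membership is decided by gene-symbol prefix on the motif's
    mapped gene(s). Idempotent; raises when no motif matches, because
    the downstream cooperativity test is undefined without ETS.
    """
    rule = rule or EtsCollapseRule()
    members = [m for m in ann.motifs if rule.matches(m, ann.motif_to_gene.get(m, []))]
    if not members:
        raise ValueError("no motif matches any ETS family prefix")
    union = ann.incidence[members].any(axis=1)
    others = [m for m in ann.motifs if m not in members]
    inc = ann.incidence[others].copy()
    inc[rule.merged] = union
    genes = sorted({g for m in members for g in ann.motif_to_gene.get(m, [m])})
    gene_map = {m: list(ann.motif_to_gene[m]) for m in others}
    gene_map[rule.merged] = genes or [rule.merged]
    return MotifAnnotation(inc, gene_map)


@dataclass
class PeakPartition:
    """Disjoint peak sets for one candidate motif versus ETS."""

    candidate: str
    both: pd.Index
    candidate_only: pd.Index
    ets_only: pd.Index
    flags: list[str] = field(default_factory=list)

    def sizes(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "candidate_only": len(self.candidate_only),
            "ets_only": len(self.ets_only),
        }


def partition_peaks(
    ann: MotifAnnotation, candidate: str, ets_name: str = "ETS"
) -> PeakPartition:
    """Split peaks by co-occurrence of the candidate and the ETS motif."""
    if candidate == ets_name:
        raise ValueError("candidate must differ from the collapsed ETS identifier")
    for name in (candidate, ets_name):
        if name not in ann.motifs:
            raise KeyError(f"motif {name!r} not in annotation")
    c = ann.incidence[candidate]
    e = ann.incidence[ets_name]
    part = PeakPartition(
        candidate=candidate,
        both=ann.peaks[(c & e).to_numpy()],
        candidate_only=ann.peaks[(c & ~e).to_numpy()],
        ets_only=ann.peaks[(~c & e).to_numpy()],
    )
    for name, idx in (
        ("both", part.both),
        ("candidate_only", part.candidate_only),
        ("ets_only", part.ets_only),
    ):
        if len(idx) == 0:
            part.flags.append(f"empty:{name}")
    return part


def _partition_deviations(
    counts: CountMatrix, part: PeakPartition, backgrounds: np.ndarray
) -> DeviationResult:
    inc = pd.DataFrame(
        {
            "both": counts.features.isin(part.both),
            "candidate_only": counts.features.isin(part.candidate_only),
            "ets_only": counts.features.isin(part.ets_only),
        },
        index=counts.features,
    )
    return compute_deviations(counts, MotifAnnotation(inc), backgrounds)


def _test_record(part: PeakPartition, z: pd.DataFrame, min_peaks: int) -> dict:
    """Rank-sum comparisons on a partitions x cells z table."""
    rec: dict = {"candidate": part.candidate, **{f"n_{k}": v for k, v in part.sizes().items()}}

    def _z(name: str) -> np.ndarray:
        vals = z.loc[name].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    z_both = _z("both")
    rec["median_z_both"] = float(np.median(z_both)) if z_both.size else np.nan
    for other, key in (("ets_only", "p_vs_ets_only"), ("candidate_only", "p_vs_candidate_only")):
        n_other = rec[f"n_{other}"]
        z_other = _z(other)
        rec[f"median_z_{other}"] = float(np.median(z_other)) if z_other.size else np.nan
        if rec["n_both"] < min_peaks or n_other < min_peaks:
            rec[key] = np.nan
            rec[f"skip_{key}"] = (
                f"partition below minimum size ({min_peaks}): "
                f"both={rec['n_both']}, {other}={n_other}"
            )
            continue
        if z_both.size == 0 or z_other.size == 0:
            rec[key] = np.nan
            rec[f"skip_{key}"] = "no finite z-scores"
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec[key] = float(
                stats.mannwhitneyu(z_both, z_other, alternative="greater", method="auto").pvalue
            )
    return rec


def coaccessibility_test(
    counts: CountMatrix,
    part: PeakPartition,
    backgrounds: np.ndarray,
    cells: pd.Index | Sequence | None = None,
    min_peaks: int = 5,
) -> dict:
    """One candidate's cooperativity test within a cell subset.

    Each partition set is treated as a pseudo-annotation and scored
    with per-cell deviation z; the record carries partition sizes,
    median z per partition, and the two one-sided rank-sum p-values
    (BOTH vs ETS_ONLY — the headline comparison — and BOTH vs C_ONLY).
    Partitions below ``min_peaks`` peaks skip the corresponding test
    with a reason.
    """
    dev = _partition_deviations(counts, part, backgrounds)
    cells = pd.Index(cells) if cells is not None else dev.cells
    return _test_record(part, dev.z.loc[:, cells], min_peaks)


@dataclass
class CoAccessResult:
    """Cooperativity test results across candidate motifs in one cell subset."""

    table: pd.DataFrame
    cell_subset: str
    z_distributions: dict[str, pd.DataFrame]  # candidate -> partitions x cells z table

    def summary(self) -> str:
        cols = [
            "candidate",
            "n_both",
            "n_ets_only",
            "n_candidate_only",
            "median_z_both",
            "median_z_ets_only",
            "p_vs_ets_only",
            "q_vs_ets_only",
        ]
        lines = [f"Motif co-accessibility vs ETS (cells: {self.cell_subset})", ""]
        with pd.option_context("display.width", 120):
            lines.append(self.table[cols].to_string(index=False, float_format="%.4g"))
        return "\n".join(lines)


class CooperativityTest:
    """Model object for the ETS cooperativity analysis.

    Built from a peak-by-cell count matrix, a motif annotation (ETS
    collapse applied on construction), matched background peak sets and
    per-cell labels; ``fit`` runs the partitioned deviation test for
    the requested candidates within one cell subset and BH-adjusts
    across candidates.
    """

    def __init__(
        self,
        counts: CountMatrix,
        annotation: MotifAnnotation,
        backgrounds: np.ndarray,
        cell_labels: pd.Series | None = None,
        rule: EtsCollapseRule | None = None,
    ):
        self.counts = counts
        self.rule = rule or EtsCollapseRule()
        self.annotation = collapse_ets(annotation, self.rule)
        self.backgrounds = backgrounds
        self.cell_labels = (
            cell_labels.reindex(counts.cells) if cell_labels is not None else None
        )

    def fit(
        self,
        candidates: Sequence[str] | None = None,
        cell_type: Optional[str] = None,
        min_peaks: int = 5,
    ) -> CoAccessResult:
        ets = self.rule.merged
        if candidates is None:
            candidates = [m for m in self.annotation.motifs if m != ets]
        if cell_type is not None:
            if self.cell_labels is None:
                raise ValueError("cell_type requested but no cell labels were given")
            cells = self.counts.cells[(self.cell_labels == cell_type).to_numpy()]
            subset_name = str(cell_type)
        else:
            cells = self.counts.cells
            subset_name = "all"
        if len(cells) == 0:
            raise ValueError(f"no cells in subset {subset_name!r}")

        records, z_dists = [], {}
        for cand in candidates:
            part = partition_peaks(self.annotation, cand, ets)
            dev = _partition_deviations(self.counts, part, self.backgrounds)
            z = dev.z.loc[:, cells]
            z_dists[cand] = z
            records.append(_test_record(part, z, min_peaks))
        table = pd.DataFrame(records)
        for raw, adj in (
            ("p_vs_ets_only", "q_vs_ets_only"),
            ("p_vs_candidate_only", "q_vs_candidate_only"),
        ):
            table[adj] = np.nan
            ok = table[raw].notna()
            if ok.any():
                table.loc[ok, adj] = multipletests(table.loc[ok, raw], method="fdr_bh")[1]
        return CoAccessResult(table=table, cell_subset=subset_name, z_distributions=z_dists)
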