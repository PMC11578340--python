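"""Promoter-coverage (TSS score) analysis of cfDNA fragment depth.

The TSS score of a gene in a sample is the mean fragment depth over the
core window [tss - 250, tss + 250) divided by the mean depth over the
flanking windows [tss - 500, tss - 250) and [tss + 250, tss + 500). Depth
counts whole fragment spans. Because both windows are symmetric around the
TSS the score is strand-invariant, and a high score marks low expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragment_io import FragmentFrame, _coerce_frame
from . import evaluation


class TssError(ValueError):
    pass


@dataclass(frozen=True)
class TssAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 0-based position
    strand: str = "+"


@dataclass(frozen=True)
class TssScore:
    sample_id: str
    gene_id: str
    core_mean_depth: float
    flank_mean_depth: float
    scorable: bool = True

    @property
    def defined(self) -> bool:
        return self.scorable and self.flank_mean_depth > 0

    @property
    def score(self) -> float:
        if not self.defined:
            return math.nan
        return self.core_mean_depth / self.flank_mean_depth


def read_tss_table(path) -> list[TssAnnotation]:
    """Read TSS annotations from the 4-column table or BED6.

    Table columns: gene_id, chrom, tss_position (0-based), strand, with an
    optional ``#`` header. BED6 rows are detected by column count; the TSS
    is the interval start for + genes and end - 1 for - genes.
    """
    annotations = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 4:
                gene_id, chrom, pos, strand = parts
                tss = int(pos)
            elif len(parts) >= 6:
                chrom, start, end, gene_id, _score, strand = parts[:6]
                tss = int(start) if strand == "+" else int(end) - 1
            else:
                raise TssError(f"unrecognized TSS annotation row: {line!r}")
            annotations.append(TssAnnotation(gene_id, chrom, tss, strand))
    return annotations


def write_tss_table(annotations: Iterable[TssAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\ttss\tstrand\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.chrom}\t{a.tss}\t{a.strand}\n")


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------


def depth_profile(fragments, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base fragment-level depth over [start, end) on ``chrom``.

    Position ``i`` of the result counts fragments whose interval covers base
    ``start + i`` (whole span, not read ends).
    """
    if start < 0 or end <= start:
        raise TssError(f"invalid window [{start}, {end})")
    frame = _coerce_frame(fragments)
    width = end - start
    delta = np.zeros(width + 1, dtype=np.int64)
    mask = frame.chrom_mask(chrom)
    s = np.clip(frame.start[mask], start, end) - start
    e = np.clip(frame.end[mask], start, end) - start
    keep = s < e
    np.add.at(delta, s[keep], 1)
    np.add.at(delta, e[keep], -1)
    return np.cumsum(delta)[:width]


def _window_bounds(annotation: TssAnnotation, core_halfwidth, flank_inner, flank_outer):
    t = annotation.tss
    core = (t - core_halfwidth, t + core_halfwidth)
    flank_left = (t - flank_outer, t - flank_inner)
    flank_right = (t + flank_inner, t + flank_outer)
    return core, flank_left, flank_right


def tss_score(
    fragments,
    annotation: TssAnnotation,
    chrom_length: int,
    core_halfwidth: int = 250,
    flank_inner: int = 250,
    flank_outer: int = 500,
    sample_id: str = "sample",
) -> TssScore:
    """Score one gene in one sample; out-of-bounds windows are flagged
    unscorable rather than raising."""
    core, fl, fr = _window_bounds(annotation, core_halfwidth, flank_inner, flank_outer)
    if fl[0] < 0 or fr[1] > chrom_length:
        return TssScore(sample_id, annotation.gene_id, 0.0, 0.0, scorable=False)
    depth = depth_profile(fragments, annotation.chrom, fl[0], fr[1])
    offset = fl[0]
    core_depth = depth[core[0] - offset : core[1] - offset]
    flank_depth = np.concatenate(
        [depth[: fl[1] - offset], depth[fr[0] - offset :]]
    )
    return TssScore(
        sample_id=sample_id,
        gene_id=annotation.gene_id,
        core_mean_depth=float(core_depth.mean()),
        flank_mean_depth=float(flank_depth.mean()),
    )


def tss_score_matrix(
    frames: Mapping[str, "FragmentFrame"],
    annotations: Sequence[TssAnnotation],
    chrom_lengths: Mapping[str, int],
    core_halfwidth: int = 250,
    flank_inner: int = 250,
    flank_outer: int = 500,
) -> pd.DataFrame:
    """Genes x samples matrix of TSS scores (NaN where undefined).

    Uses one cumulative-depth pass per (sample, chromosome), so scoring many
    genes is cheap.
    """
    gene_ids = [a.gene_id for a in annotations]
    out = pd.DataFrame(index=gene_ids, columns=list(frames), dtype=float)
    for sample_id, frame in frames.items():
        prefix_by_chrom: dict[str, np.ndarray] = {}
        for chrom in {a.chrom for a in annotations}:
            length = chrom_lengths[chrom]
            delta = np.zeros(length + 1, dtype=np.int64)
            mask = frame.chrom_mask(chrom)
            s = np.clip(frame.start[mask], 0, length)
            e = np.clip(frame.end[mask], 0, length)
            np.add.at(delta, s, 1)
            np.add.at(delta, e, -1)
            depth = np.cumsum(delta)[:length]
            prefix_by_chrom[chrom] = np.concatenate([[0], np.cumsum(depth)])
        for ann in annotations:
            length = chrom_lengths[ann.chrom]
            core, fl, fr = _window_bounds(ann, core_halfwidth, flank_inner, flank_outer)
            if fl[0] < 0 or fr[1] > length:
                out.loc[ann.gene_id, sample_id] = np.nan
                continue
            prefix = prefix_by_chrom[ann.chrom]
            core_sum = prefix[core[1]] - prefix[core[0]]
            flank_sum = (prefix[fl[1]] - prefix[fl[0]]) + (prefix[fr[1]] - prefix[fr[0]])
            core_mean = core_sum / (core[1] - core[0])
            flank_mean = flank_sum / ((fl[1] - fl[0]) + (fr[1] - fr[0]))
            out.loc[ann.gene_id, sample_id] = (
                core_mean / flank_mean if flank_mean > 0 else np.nan
            )
    return out


# ---------------------------------------------------------------------------
# differential TSS and per-gene AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentialTssResult:
    gene_id: str
    log2_fold_change: float  # non-responder over responder mean score
    p_value: float
    q_value: float
    direction: str  # increased / decreased / none


def differential_tss(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> tuple[list[DifferentialTssResult], list[str]]:
    """Per-gene Mann-Whitney U on TSS scores; closed thresholds (>= / <=).

    ``group_a`` (responders) and ``group_b`` (non-responders) are genes x
    samples matrices. Genes with fewer than two defined scores in either
    group are excluded and returned in the second element.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise TssError("differential test requires >= 2 samples per group")
    genes = [g for g in group_a.index if g in set(group_b.index)]
    raw: list[tuple[str, float, float]] = []
    excluded: list[str] = []
    for gene in genes:
        va = group_a.loc[gene].to_numpy(dtype=float)
        vb = group_b.loc[gene].to_numpy(dtype=float)
        va = va[~np.isnan(va)]
        vb = vb[~np.isnan(vb)]
        if va.size < 2 or vb.size < 2:
            excluded.append(gene)
            continue
        res = evaluation.mann_whitney_u(va, vb)
        mean_a = float(va.mean())
        mean_b = float(vb.mean())
        if mean_a <= 0 or mean_b <= 0:
            excluded.append(gene)
            continue
        raw.append((gene, float(np.log2(mean_b / mean_a)), res.p_value))
    qvals = evaluation.bh_adjust([p for _, _, p in raw]) if raw else np.zeros(0)
    results = []
    for (gene, lfc, p), q in zip(raw, qvals):
        if p < alpha and lfc >= lfc_threshold:
            direction = "increased"
        elif p < alpha and lfc <= -lfc_threshold:
            direction = "decreased"
        else:
            direction = "none"
        results.append(DifferentialTssResult(gene, lfc, p, float(q), direction))
    return results, excluded


def differential_tss_table(results: Sequence[DifferentialTssResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log2fc": [r.log2_fold_change for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "direction": [r.direction for r in results],
        }
    )


@dataclass(frozen=True)
class GeneSetOverlap:
    overlap: tuple[str, ...]
    left_only: tuple[str, ...]
    right_only: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "overlap": len(self.overlap),
            "left_only": len(self.left_only),
            "right_only": len(self.right_only),
        }

    def as_dict(self) -> dict:
        return {
            "overlap": list(self.overlap),
            "left_only": list(self.left_only),
            "right_only": list(self.right_only),
            "counts": self.counts,
        }


def gene_set_overlap(
    differential_genes: Iterable[str], reference_list: Iterable[str]
) -> GeneSetOverlap:
    """Exact two-set intersection (case-sensitive, whitespace-normalized)."""
    left = {str(g).strip() for g in differential_genes}
    right = {str(g).strip() for g in reference_list}
    return GeneSetOverlap(
        overlap=tuple(sorted(left & right)),
        left_only=tuple(sorted(left - right)),
        right_only=tuple(sorted(right - left)),
    )


@dataclass(frozen=True)
class GeneAuc:
    gene_id: str
    auc: float  # oriented, max(raw, 1 - raw)
    raw_auc: float  # non-responder-high orientation
    direction: str  # high/low in non-responders


def per_gene_auc(
    scores: Sequence[float],
    labels: Sequence,
    gene_id: str = "gene",
    positive_label=evaluation.NON_RESPONDER,
) -> GeneAuc:
    """Discriminative AUC of one gene's TSS scores, reported in its better
    orientation with a direction flag."""
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    keep = ~np.isnan(scores)
    scores = scores[keep]
    labels = [lab for lab, k in zip(labels, keep) if k]
    n_pos = sum(lab == positive_label for lab in labels)
    if n_pos < 2 or len(labels) - n_pos < 2:
        raise TssError("per-gene AUC requires >= 2 samples per class")
    raw = evaluation.roc_auc(
        scores, labels, positive_label=positive_label, n_bootstrap=0
    ).auc
    if raw >= 0.5:
        return GeneAuc(gene_id, raw, raw, "high in non-responders")
    return GeneAuc(gene_id, 1.0 - raw, raw, "low in non-responders")
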