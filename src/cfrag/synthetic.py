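"""Self-contained synthetic cohort generator with known ground truth.

Generates a uniform random reference genome with spaced TSS annotations,
per-sample fragment sets whose 5' end-motif composition differs between
response groups by a configurable log2 fold change (weighted placement on
both fragment ends), promoter-core depth depletion for a designated
"expressed" gene set in the non-responder group, longitudinal cfDNA
concentration series with a post-chemotherapy spike, and a clinical table
whose tumor measurements force the intended RECIST labels. Identical
(config, seed) reproduces every output byte-identically.

Effect-size defaults sit above the differential-calling thresholds
(motif |log2fc| 0.1 vs gate 0.04; TSS depletion giving |log2fc| > 0.5) so
that recovery is testable at cohort sizes of 8-12 per group.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concentration import ConcentrationSeries, write_concentration_table
from .end_motif import (
    DNA,
    all_motifs,
    encode_sequence,
    kmer_id_array,
    motif_id,
    reverse_complement,
    revcomp_id_table,
)
from .fragment_io import FragmentFrame, write_fragments
from .tss_coverage import TssAnnotation, write_tss_table

TSS_SPACING = 1000  # min distance between generated TSSs
TSS_EDGE_MARGIN = 500  # min distance from chromosome ends
CORE_HALFWIDTH = 250  # depletion window matches the scoring core window

FIGO_STAGES = ("IB3", "IIA1", "IIA2", "IIB", "IIIA", "IIIB", "IIIC1")
HISTOLOGIES = ("SCC", "SCC", "SCC", "SCC", "AC")  # SCC-dominant mix


class SyntheticConfigError(ValueError):
    pass


class SizingError(SyntheticConfigError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 200_000
    n_genes: int = 60
    n_expressed_genes: int = 10
    n_responders: int = 12
    n_nonresponders: int = 8
    fragments_per_sample: int = 20_000
    fragment_length_mean: int = 167
    fragment_length_sd: float = 30.0
    fragment_length_min: int = 50
    fragment_length_max: int = 599
    motif_effect_log2fc: float = 0.1
    n_increased_motifs: int = 11
    n_decreased_motifs: int = 12
    tss_depletion_depth_fraction: float = 0.6
    concentration_baseline_mean: float = 5.0
    concentration_spike_fold_nonresponder: float = 3.0
    concentration_spike_fold_responder: float = 1.2
    noise_dispersion: float = 0.15
    scc_response_effect: float = 0.4
    filter_fail_fraction: float = 0.02

    def validate(self) -> None:
        problems = []
        positive_ints = (
            "n_chromosomes",
            "chromosome_length",
            "n_genes",
            "n_responders",
            "n_nonresponders",
            "fragments_per_sample",
            "fragment_length_mean",
        )
        for name in positive_ints:
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be strictly positive")
        if self.fragment_length_sd < 0 or self.noise_dispersion < 0:
            problems.append("dispersions must be non-negative")
        if not 0 <= self.n_expressed_genes <= self.n_genes:
            problems.append("n_expressed_genes must be in [0, n_genes]")
        if self.n_increased_motifs + self.n_decreased_motifs > 256:
            problems.append("n_increased_motifs + n_decreased_motifs must be <= 256")
        if self.n_increased_motifs < 1 or self.n_decreased_motifs < 1:
            problems.append("motif set sizes must be >= 1")
        if not 0 <= self.tss_depletion_depth_fraction <= 1:
            problems.append("tss_depletion_depth_fraction must be in [0, 1]")
        if not 0 <= self.filter_fail_fraction < 0.5:
            problems.append("filter_fail_fraction must be in [0, 0.5)")
        if not (
            0 < self.fragment_length_min
            <= self.fragment_length_mean
            <= self.fragment_length_max
        ):
            problems.append("fragment length bounds must bracket the mean")
        if self.concentration_baseline_mean <= 0:
            problems.append("concentration_baseline_mean must be > 0")
        if (
            self.concentration_spike_fold_nonresponder <= 0
            or self.concentration_spike_fold_responder <= 0
        ):
            problems.append("spike folds must be > 0")
        if problems:
            raise SyntheticConfigError("; ".join(problems))

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        return cls(**dict(data))


@dataclass(frozen=True)
class GroundTruth:
    increased_motif_set: tuple[str, ...]
    decreased_motif_set: tuple[str, ...]
    expressed_gene_set: tuple[str, ...]
    per_sample_labels: dict[str, str]  # sample id -> responder / non-responder

    def as_dict(self) -> dict:
        return {
            "increased_motif_set": list(self.increased_motif_set),
            "decreased_motif_set": list(self.decreased_motif_set),
            "expressed_gene_set": list(self.expressed_gene_set),
            "per_sample_labels": dict(self.per_sample_labels),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "GroundTruth":
        return cls(
            increased_motif_set=tuple(data["increased_motif_set"]),
            decreased_motif_set=tuple(data["decreased_motif_set"]),
            expressed_gene_set=tuple(data["expressed_gene_set"]),
            per_sample_labels=dict(data["per_sample_labels"]),
        )


@dataclass
class Reference:
    sequences: dict[str, str]
    tss: list[TssAnnotation]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def _rng(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config_seed, spawn_key=key))


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def simulate_reference(config: SyntheticConfig) -> Reference:
    """Uniform-composition genome plus TSS annotations on a >= 1 kb grid,
    each >= 500 bp from chromosome ends."""
    config.validate()
    rng = _rng(config.seed, 0)
    sequences: dict[str, str] = {}
    bases = np.frombuffer(DNA.encode(), dtype=np.uint8)
    for i in range(config.n_chromosomes):
        codes = rng.integers(0, 4, size=config.chromosome_length)
        sequences[f"chr{i + 1}"] = bases[codes].tobytes().decode("ascii")

    candidates: list[tuple[str, int]] = []
    for chrom in sequences:
        pos = TSS_EDGE_MARGIN
        while pos + TSS_EDGE_MARGIN <= config.chromosome_length:
            candidates.append((chrom, pos))
            pos += TSS_SPACING
    if config.n_genes > len(candidates):
        raise SizingError(
            f"cannot place {config.n_genes} genes: only {len(candidates)} positions "
            f"satisfy {TSS_SPACING} bp spacing and {TSS_EDGE_MARGIN} bp edge margins"
        )
    chosen = sorted(rng.choice(len(candidates), size=config.n_genes, replace=False))
    strands = rng.choice(np.array(["+", "-"], dtype=object), size=config.n_genes)
    width = len(str(config.n_genes))
    tss = [
        TssAnnotation(
            gene_id=f"GENE{j + 1:0{width}d}",
            chrom=candidates[c][0],
            tss=candidates[c][1],
            strand=strands[j],
        )
        for j, c in enumerate(chosen)
    ]
    return Reference(sequences=sequences, tss=tss)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def sample_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    responders = [f"R{i + 1:02d}" for i in range(config.n_responders)]
    nonresponders = [f"N{i + 1:02d}" for i in range(config.n_nonresponders)]
    return responders, nonresponders


def choose_ground_truth(reference: Reference, config: SyntheticConfig) -> GroundTruth:
    """Pick the planted motif sets (increased start with A/G, decreased with
    C), the depleted gene set, and the sample labels.

    Raises :class:`GenerationError` if a designated motif can never be
    observed on the reference (absent both as a forward 4-mer and as the
    reverse complement of one).
    """
    rng = _rng(config.seed, 1)
    motifs = all_motifs(4)
    ag_pool = [m for m in motifs if m[0] in "AG"]
    c_pool = [m for m in motifs if m[0] == "C"]
    if config.n_increased_motifs > len(ag_pool) or config.n_decreased_motifs > len(c_pool):
        raise SyntheticConfigError(
            "motif set sizes exceed the A/G-starting or C-starting pools"
        )
    increased = tuple(
        sorted(rng.choice(ag_pool, size=config.n_increased_motifs, replace=False))
    )
    decreased = tuple(
        sorted(rng.choice(c_pool, size=config.n_decreased_motifs, replace=False))
    )

    forward_counts = np.zeros(256, dtype=np.int64)
    for seq in reference.sequences.values():
        ids, valid = kmer_id_array(encode_sequence(seq), 4)
        forward_counts += np.bincount(ids[valid], minlength=256)
    for motif in increased + decreased:
        observable = (
            forward_counts[motif_id(motif)] + forward_counts[motif_id(reverse_complement(motif))]
        )
        if observable == 0:
            raise GenerationError(f"motif {motif} is absent from the reference genome")

    gene_ids = [a.gene_id for a in reference.tss]
    expressed = tuple(
        sorted(rng.choice(gene_ids, size=config.n_expressed_genes, replace=False))
    )
    responders, nonresponders = sample_ids(config)
    labels = {sid: "responder" for sid in responders}
    labels.update({sid: "non-responder" for sid in nonresponders})
    return GroundTruth(
        increased_motif_set=increased,
        decreased_motif_set=decreased,
        expressed_gene_set=expressed,
        per_sample_labels=labels,
    )


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------


class _ReferenceIndex:
    """Precomputed arrays for fast weighted fragment placement."""

    def __init__(self, reference: Reference):
        self.chrom_names = list(reference.sequences)
        lengths = np.array([len(reference.sequences[c]) for c in self.chrom_names])
        self.lengths = lengths
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.total = int(self.offsets[-1])
        # forward 4-mer id at every concatenated position (last 3 of each
        # chromosome are unused because fragment ends stay in-bounds)
        ids = np.zeros(self.total, dtype=np.int64)
        for i, chrom in enumerate(self.chrom_names):
            chrom_ids, _valid = kmer_id_array(
                encode_sequence(reference.sequences[chrom]), 4
            )
            ids[self.offsets[i] : self.offsets[i] + len(chrom_ids)] = chrom_ids
        self.kmer_ids = ids

    def depletion_mask(self, reference: Reference, genes: Sequence[str]) -> np.ndarray:
        mask = np.zeros(self.total, dtype=bool)
        wanted = set(genes)
        index = {c: i for i, c in enumerate(self.chrom_names)}
        for ann in reference.tss:
            if ann.gene_id in wanted:
                off = self.offsets[index[ann.chrom]]
                lo = max(0, ann.tss - CORE_HALFWIDTH)
                hi = min(self.lengths[index[ann.chrom]], ann.tss + CORE_HALFWIDTH)
                mask[off + lo : off + hi] = True
        return mask


def _index_for(reference: Reference) -> _ReferenceIndex:
    cached = getattr(reference, "_frag_index", None)
    if cached is None:
        cached = _ReferenceIndex(reference)
        reference._frag_index = cached  # type: ignore[attr-defined]
    return cached


def simulate_fragments(
    reference: Reference,
    truth: GroundTruth,
    group_label: str,
    config: SyntheticConfig,
    sample_seed: int,
) -> FragmentFrame:
    """One sample's fragments with the group's planted effects.

    Non-responder samples over-represent the increased motif set by
    ``motif_effect_log2fc`` at both fragment 5' ends (weighted placement
    with symmetric under-representation of the decreased set) and deplete
    coverage at expressed-gene promoter cores by
    ``tss_depletion_depth_fraction`` (midpoint thinning). A
    ``filter_fail_fraction`` minority per retention rule is injected with
    failing QC values.
    """
    if group_label not in ("responder", "non-responder"):
        raise SyntheticConfigError(f"unknown group label {group_label!r}")
    config.validate()
    rng = np.random.default_rng(sample_seed)
    index = _index_for(reference)
    rc_table = revcomp_id_table(4)

    weights = np.ones(256)
    if group_label == "non-responder" and config.motif_effect_log2fc != 0:
        for m in truth.increased_motif_set:
            weights[motif_id(m)] = 2.0 ** config.motif_effect_log2fc
        for m in truth.decreased_motif_set:
            weights[motif_id(m)] = 2.0 ** -config.motif_effect_log2fc
    w_max = float(weights.max()) ** 2

    deplete = (
        group_label == "non-responder"
        and config.tss_depletion_depth_fraction < 1.0
        and truth.expressed_gene_set
    )
    depletion = (
        index.depletion_mask(reference, truth.expressed_gene_set) if deplete else None
    )
    frac = config.tss_depletion_depth_fraction

    n_target = config.fragments_per_sample
    starts_acc: list[np.ndarray] = []
    ends_acc: list[np.ndarray] = []
    have = 0
    while have < n_target:
        batch = max(2048, int((n_target - have) * 1.8))
        pos = rng.integers(0, index.total, size=batch)
        lengths = np.rint(
            rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=batch)
        ).astype(np.int64)
        chrom_idx = np.searchsorted(index.offsets, pos, side="right") - 1
        local = pos - index.offsets[chrom_idx]
        ok = (
            (lengths >= config.fragment_length_min)
            & (lengths <= config.fragment_length_max)
            & (local + lengths <= index.lengths[chrom_idx])
        )
        pos, lengths = pos[ok], lengths[ok]
        w = weights[index.kmer_ids[pos]] * weights[rc_table[index.kmer_ids[pos + lengths - 4]]]
        accept = rng.random(len(pos)) * w_max < w
        if depletion is not None:
            mid = pos + lengths // 2
            accept &= ~depletion[mid] | (rng.random(len(pos)) < frac)
        starts_acc.append(pos[accept])
        ends_acc.append((pos + lengths)[accept])
        have += int(accept.sum())

    start_cat = np.concatenate(starts_acc)[:n_target]
    end_cat = np.concatenate(ends_acc)[:n_target]
    chrom_idx = np.searchsorted(index.offsets, start_cat, side="right") - 1
    start_local = start_cat - index.offsets[chrom_idx]
    end_local = end_cat - index.offsets[chrom_idx]

    n = n_target
    mapq = rng.integers(30, 61, size=n)
    mismatches = np.minimum(rng.poisson(0.5, size=n), 5)
    proper = np.ones(n, dtype=bool)
    duplicate = np.zeros(n, dtype=bool)
    multimapped = np.zeros(n, dtype=bool)
    strand = rng.choice(np.array(["+", "-"], dtype=object), size=n)

    n_fail = int(round(config.filter_fail_fraction * n))
    if n_fail:
        perm = rng.permutation(n)
        slots = [perm[i * n_fail : (i + 1) * n_fail] for i in range(6)]
        mapq[slots[0]] = rng.integers(0, 30, size=len(slots[0]))
        mismatches[slots[1]] = 6 + rng.poisson(1.0, size=len(slots[1]))
        proper[slots[2]] = False
        duplicate[slots[3]] = True
        multimapped[slots[4]] = True
        # oversized inserts: >= 600 bp, shifted left if the chromosome ends
        long_len = rng.integers(600, 650, size=len(slots[5]))
        lim = index.lengths[chrom_idx[slots[5]]]
        new_start = np.minimum(start_local[slots[5]], lim - long_len)
        start_local[slots[5]] = np.maximum(new_start, 0)
        end_local[slots[5]] = start_local[slots[5]] + long_len

    order = np.lexsort((start_local, chrom_idx))
    chrom_names = np.array(index.chrom_names, dtype=object)
    return FragmentFrame(
        chrom=chrom_names[chrom_idx[order]],
        start=start_local[order],
        end=end_local[order],
        strand=strand[order],
        mapq=mapq[order],
        mismatches=mismatches[order],
        proper_pair=proper[order],
        duplicate=duplicate[order],
        multimapped=multimapped[order],
    )


def depth_fraction_for_score_fold(
    target_score_fold: float, config: SyntheticConfig
) -> float:
    """Depth multiplier that yields ~``target_score_fold`` as the realized
    TSS score after midpoint-thinning smearing.

    Thinning acts on fragment midpoints, so depletion bleeds across window
    edges by about half a fragment length; this inverts that smearing for
    the configured mean fragment length and the 250/250-500 bp windows.
    """
    if not 0 < target_score_fold <= 1:
        raise SyntheticConfigError("target score fold must be in (0, 1]")
    length = config.fragment_length_mean
    half = length / 2.0
    core_lo, core_hi = -CORE_HALFWIDTH, CORE_HALFWIDTH

    def overlap_fraction(x: float) -> float:
        lo = max(x - half, core_lo)
        hi = min(x + half, core_hi)
        return max(0.0, hi - lo) / length

    xs_core = np.arange(core_lo, core_hi) + 0.5
    xs_flank = np.concatenate(
        [np.arange(-500, core_lo), np.arange(core_hi, 500)]
    ) + 0.5
    a = float(np.mean([overlap_fraction(x) for x in xs_core]))
    b = float(np.mean([overlap_fraction(x) for x in xs_flank]))
    t = target_score_fold
    u = (1.0 - t) / (a - t * b)
    return float(np.clip(1.0 - u, 0.0, 1.0))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortBundle:
    config: SyntheticConfig
    reference: Reference
    truth: GroundTruth
    fragments: dict[str, FragmentFrame]
    concentrations: list[ConcentrationSeries]
    clinical: pd.DataFrame


def _simulate_concentrations(
    labels: Mapping[str, str], config: SyntheticConfig, rng: np.random.Generator
) -> list[ConcentrationSeries]:
    series = []
    noise = config.noise_dispersion
    for pid in labels:
        spike = (
            config.concentration_spike_fold_nonresponder
            if labels[pid] == "non-responder"
            else config.concentration_spike_fold_responder
        )
        t1 = config.concentration_baseline_mean * float(np.exp(rng.normal(0, max(noise, 1e-12))))
        t2 = t1 * spike * float(np.exp(rng.normal(0, noise))) if noise > 0 else t1 * spike
        t3 = t1 * float(np.exp(rng.normal(0, noise))) if noise > 0 else t1
        t4 = t1 * float(np.exp(rng.normal(0, noise))) if noise > 0 else t1
        series.append(
            ConcentrationSeries(pid, {"T1": t1, "T2": t2, "T3": t3, "T4": t4})
        )
    return series


def _simulate_clinical(
    labels: Mapping[str, str], config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    eff = config.scc_response_effect
    for pid, label in labels.items():
        responder = label == "responder"
        initial = float(rng.uniform(2.0, 6.5))
        if responder:
            reduction = float(rng.uniform(32.0, 75.0))
            new_lesions = False
        else:
            reduction = float(rng.uniform(-15.0, 25.0))
            new_lesions = bool(rng.random() < 0.25)
        post = initial * (1.0 - reduction / 100.0)
        is_nr = 0.0 if responder else 1.0
        scc1 = float(np.exp(rng.normal(np.log(4.0), 0.5)))
        scc2 = scc1 * float(np.exp(rng.normal(0.0, 0.3) + 0.5 * eff * is_nr))
        scc3 = scc1 * float(np.exp(rng.normal(0.0, 0.3) + eff * is_nr))
        rows.append(
            {
                "patient_id": pid,
                "age": int(rng.integers(30, 70)),
                "figo_stage": str(rng.choice(FIGO_STAGES)),
                "histology": str(rng.choice(HISTOLOGIES)),
                "initial_diameter_cm": round(initial, 2),
                "post_cycle2_diameter_cm": round(post, 2),
                "new_lesions": int(new_lesions),
                "scc_ag_pretreatment": round(scc1, 3),
                "scc_ag_after_cycle1": round(scc2, 3),
                "scc_ag_after_cycle2": round(scc3, 3),
                "flags": "",
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Full synthetic study: reference, ground truth, per-sample fragments,
    concentration series and clinical covariates."""
    config.validate()
    reference = simulate_reference(config)
    truth = choose_ground_truth(reference, config)
    fragments: dict[str, FragmentFrame] = {}
    for i, (sid, label) in enumerate(sorted(truth.per_sample_labels.items())):
        sample_rng = _rng(config.seed, 2, i)
        sample_seed = int(sample_rng.integers(0, 2**63 - 1))
        fragments[sid] = simulate_fragments(reference, truth, label, config, sample_seed)
    concentrations = _simulate_concentrations(
        truth.per_sample_labels, config, _rng(config.seed, 3)
    )
    clinical = _simulate_clinical(truth.per_sample_labels, config, _rng(config.seed, 4))
    return CohortBundle(
        config=config,
        reference=reference,
        truth=truth,
        fragments=fragments,
        concentrations=concentrations,
        clinical=clinical,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_reference_fasta(reference: Reference, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cohort(bundle: CohortBundle, out_dir) -> dict[str, str]:
    """Write every cohort artifact as plain text; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    ref_path = out / "reference.fa"
    write_reference_fasta(bundle.reference, ref_path)
    paths["reference"] = str(ref_path)

    tss_path = out / "tss.tsv"
    write_tss_table(bundle.reference.tss, tss_path)
    paths["tss"] = str(tss_path)

    frag_dir = out / "fragments"
    frag_dir.mkdir(exist_ok=True)
    for sid, frame in bundle.fragments.items():
        fpath = frag_dir / f"{sid}.tsv"
        write_fragments(frame, fpath)
        paths[f"fragments/{sid}"] = str(fpath)

    conc_path = out / "concentrations.tsv"
    write_concentration_table(bundle.concentrations, conc_path)
    paths["concentrations"] = str(conc_path)

    clin_path = out / "clinical.tsv"
    bundle.clinical.to_csv(clin_path, sep="\t", index=False)
    paths["clinical"] = str(clin_path)

    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(bundle.truth.as_dict(), indent=2, sort_keys=True))
    paths["ground_truth"] = str(truth_path)

    config_path = out / "config.json"
    config_path.write_text(json.dumps(bundle.config.as_dict(), indent=2, sort_keys=True))
    paths["config"] = str(config_path)
    return paths
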