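"""4-mer 5' end-motif profiling of cfDNA fragments.

Each retained fragment contributes two 5' ends: the plus-strand end motif
is the reference sequence at ``[start, start + k)`` and the minus-strand
end motif is the reverse complement of the reference at ``[end - k, end)``.
Motifs are taken from the reference genome (not read bases). Profiles over
the 256 possible 4-mers feed a nonparametric differential analysis and the
sample-level motif-ratio statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fragment_io import FragmentFrame, _coerce_frame
from . import evaluation

DNA = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@lru_cache(maxsize=None)
def all_motifs(k: int = 4) -> tuple[str, ...]:
    """All k-mers over {A,C,G,T} in lexicographic order (256 for k=4)."""
    return tuple("".join(p) for p in itertools.product(DNA, repeat=k))


MOTIFS = all_motifs(4)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class MotifError(ValueError):
    pass


class MissingChromosomeError(MotifError):
    pass


def encode_sequence(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A=0, C=1, G=2, T=3; 255 for anything else)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_id_array(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position k-mer ids and validity over an encoded sequence.

    ``ids[i]`` is the base-4 id of ``seq[i:i+k]``; ``valid[i]`` is False
    when the window contains a non-ACGT base.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    safe = np.where(codes < 4, codes, 0).astype(np.int64)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        ids = ids * 4 + safe[i : i + n]
        valid &= codes[i : i + n] < 4
    return ids, valid


@lru_cache(maxsize=None)
def revcomp_id_table(k: int = 4) -> np.ndarray:
    """Lookup table mapping each k-mer id to its reverse complement's id."""
    table = np.zeros(4**k, dtype=np.int64)
    for mid in range(4**k):
        digits = [(mid >> (2 * (k - 1 - i))) & 3 for i in range(k)]
        rc = 0
        for d in reversed(digits):
            rc = rc * 4 + (3 - d)
        table[mid] = rc
    return table


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def motif_id(motif: str) -> int:
    mid = 0
    for b in motif:
        mid = mid * 4 + DNA.index(b)
    return mid


@dataclass
class MotifProfile:
    """Per-sample end-motif counts over all 4^k motif categories."""

    sample_id: str
    counts: np.ndarray  # shape (4**k,), int64
    ends_counted: int
    skipped_edge: int = 0
    skipped_ambiguous: int = 0
    k: int = 4

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != 4**self.k:
            raise MotifError(
                f"expected {4 ** self.k} motif categories, got {len(self.counts)}"
            )
        if int(self.counts.sum()) != self.ends_counted:
            raise MotifError("counts do not sum to ends_counted")

    @property
    def motifs(self) -> tuple[str, ...]:
        return all_motifs(self.k)

    @property
    def frequencies(self) -> np.ndarray:
        if self.ends_counted == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / float(self.ends_counted)

    def count_of(self, motif: str) -> int:
        return int(self.counts[motif_id(motif)])

    def frequency_of(self, motif: str) -> float:
        return float(self.frequencies[motif_id(motif)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=list(self.motifs), name=self.sample_id)

    def to_table(self, path) -> None:
        df = pd.DataFrame(
            {"motif": list(self.motifs), "count": self.counts, "frequency": self.frequencies}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path, sample_id: str | None = None) -> "MotifProfile":
        df = pd.read_csv(path, sep="\t")
        counts = df.set_index("motif")["count"]
        k = len(df["motif"].iloc[0])
        counts = counts.reindex(all_motifs(k), fill_value=0)
        return cls(
            sample_id=sample_id or "sample",
            counts=counts.to_numpy(),
            ends_counted=int(counts.sum()),
            k=k,
        )


def _chrom_sequence(reference: Mapping[str, str], chrom: str) -> str:
    try:
        seq = reference[chrom]
    except KeyError as exc:
        raise MissingChromosomeError(
            f"chromosome {chrom!r} absent from reference"
        ) from exc
    return str(seq)


def extract_end_motifs(
    fragments,
    reference: Mapping[str, str],
    k: int = 4,
    sample_id: str = "sample",
    both_ends: bool = True,
) -> MotifProfile:
    """Count fragment 5' end motifs against the reference.

    With ``both_ends`` (default) each fragment contributes its plus-strand
    and its minus-strand 5' end; otherwise only the 5' end of read 1's
    strand. Ends within ``k`` of a chromosome edge are skipped and tallied
    in ``skipped_edge``; ends containing a non-ACGT base are tallied in
    ``skipped_ambiguous``.
    """
    if k < 1:
        raise MotifError("k must be >= 1")
    frame = _coerce_frame(fragments)
    counts = np.zeros(4**k, dtype=np.int64)
    skipped_edge = 0
    skipped_ambiguous = 0
    rc_table = revcomp_id_table(k)
    for chrom in frame.chromosomes():
        seq = _chrom_sequence(reference, chrom)
        length = len(seq)
        ids, valid = kmer_id_array(encode_sequence(seq), k)
        mask = frame.chrom_mask(chrom)
        starts = frame.start[mask]
        ends = frame.end[mask]
        if both_ends:
            plus_pos = starts
            minus_pos = ends - k
        else:
            on_plus = frame.strand[mask] == "+"
            plus_pos = starts[on_plus]
            minus_pos = ends[~on_plus] - k
        for positions, table in ((plus_pos, None), (minus_pos, rc_table)):
            in_bounds = (positions >= 0) & (positions + k <= length)
            skipped_edge += int((~in_bounds).sum())
            pos = positions[in_bounds]
            ok = valid[pos]
            skipped_ambiguous += int((~ok).sum())
            mids = ids[pos[ok]]
            if table is not None:
                mids = table[mids]
            counts += np.bincount(mids, minlength=4**k)
    return MotifProfile(
        sample_id=sample_id,
        counts=counts,
        ends_counted=int(counts.sum()),
        skipped_edge=skipped_edge,
        skipped_ambiguous=skipped_ambiguous,
        k=k,
    )


# ---------------------------------------------------------------------------
# differential motifs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentialMotifResult:
    motif: str
    log2_fold_change: float  # group_b (non-responder) over group_a (responder)
    p_value: float
    q_value: float
    direction: str  # increased / decreased / none


def _group_center(values: np.ndarray, center: str) -> float:
    return float(np.median(values)) if center == "median" else float(np.mean(values))


def differential_motifs(
    group_a: Sequence[MotifProfile],
    group_b: Sequence[MotifProfile],
    lfc_threshold: float = 0.04,
    alpha: float = 0.05,
    center: str = "mean",
) -> list[DifferentialMotifResult]:
    """Per-motif Mann-Whitney U test of per-sample frequencies.

    ``group_a`` holds responders, ``group_b`` non-responders; fold change is
    ``group_b`` over ``group_a``. Direction is ``increased`` when
    log2 fold change > ``lfc_threshold`` with p < ``alpha`` (strict
    thresholds), ``decreased`` symmetrically, else ``none``. A group mean of
    exactly zero is replaced by the pseudo-frequency ``0.5 / mean ends``
    before taking logs. Raw p-values gate the calls; BH q-values are
    reported alongside for transparency.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise MotifError("differential test requires >= 2 samples per group")
    for prof in list(group_a) + list(group_b):
        if prof.ends_counted <= 0:
            raise MotifError(f"profile {prof.sample_id!r} has no counted ends")
    k = group_a[0].k
    freq_a = np.vstack([p.frequencies for p in group_a])
    freq_b = np.vstack([p.frequencies for p in group_b])
    pseudo_a = 0.5 / np.mean([p.ends_counted for p in group_a])
    pseudo_b = 0.5 / np.mean([p.ends_counted for p in group_b])
    motifs = all_motifs(k)
    pvals = np.empty(len(motifs))
    lfcs = np.empty(len(motifs))
    for i in range(len(motifs)):
        res = evaluation.mann_whitney_u(freq_a[:, i], freq_b[:, i])
        pvals[i] = res.p_value
        mean_a = _group_center(freq_a[:, i], center) or pseudo_a
        mean_b = _group_center(freq_b[:, i], center) or pseudo_b
        lfcs[i] = np.log2(mean_b / mean_a)
    qvals = evaluation.bh_adjust(pvals)
    results = []
    for i, motif in enumerate(motifs):
        if pvals[i] < alpha and lfcs[i] > lfc_threshold:
            direction = "increased"
        elif pvals[i] < alpha and lfcs[i] < -lfc_threshold:
            direction = "decreased"
        else:
            direction = "none"
        results.append(
            DifferentialMotifResult(
                motif=motif,
                log2_fold_change=float(lfcs[i]),
                p_value=float(pvals[i]),
                q_value=float(qvals[i]),
                direction=direction,
            )
        )
    return results


def differential_table(results: Sequence[DifferentialMotifResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif": [r.motif for r in results],
            "log2fc": [r.log2_fold_change for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "direction": [r.direction for r in results],
        }
    )


def called_motif_sets(
    results: Sequence[DifferentialMotifResult],
) -> tuple[list[str], list[str]]:
    increased = [r.motif for r in results if r.direction == "increased"]
    decreased = [r.motif for r in results if r.direction == "decreased"]
    return increased, decreased


# ---------------------------------------------------------------------------
# motif ratio and terminal-base fractions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifRatioResult:
    sample_id: str
    increased_set: tuple[str, ...]
    decreased_set: tuple[str, ...]
    numerator: float
    denominator: float

    @property
    def ratio(self) -> float:
        return self.numerator / self.denominator


def motif_ratio(
    profile: MotifProfile,
    increased_set: Iterable[str],
    decreased_set: Iterable[str],
) -> MotifRatioResult:
    """Accumulated frequency of increased motifs over that of decreased ones."""
    inc = tuple(increased_set)
    dec = tuple(decreased_set)
    if not inc or not dec:
        raise MotifError("motif sets must be non-empty")
    if set(inc) & set(dec):
        raise MotifError("increased and decreased motif sets must be disjoint")
    freqs = profile.frequencies
    numerator = float(sum(freqs[motif_id(m)] for m in inc))
    denominator = float(sum(freqs[motif_id(m)] for m in dec))
    if denominator <= 0:
        raise MotifError("motif ratio undefined: decreased-set frequency is zero")
    return MotifRatioResult(
        sample_id=profile.sample_id,
        increased_set=inc,
        decreased_set=dec,
        numerator=numerator,
        denominator=denominator,
    )


def terminal_base_fraction(profile: MotifProfile, base: str) -> float:
    """Fraction of counted ends whose motif starts with ``base``."""
    if base not in DNA:
        raise MotifError(f"base must be one of {DNA!r}")
    if profile.ends_counted <= 0:
        raise MotifError("terminal-base fraction undefined for empty profile")
    per_first_base = profile.frequencies.reshape(4, -1).sum(axis=1)
    return float(per_first_base[DNA.index(base)])
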