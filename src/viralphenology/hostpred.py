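"""Alignment-free virus-host prediction by the d2* dissimilarity.

Viruses tend to ameliorate toward the oligonucleotide composition of their
hosts, so a low compositional dissimilarity between a viral and a cellular
genome suggests an infection relationship.  d2* compares k-mer counts
after centering each genome's counts by the expectation under its own
order-m Markov chain, which removes background composition shared by
unrelated genomes.

Predictions below 0.4 are reported; below 0.2 they are higher-confidence.
A small utility also filters precomputed co-occurrence network edges at a
weight cutoff (the network inference itself is upstream of this package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KmerProfile",
    "D2StarResult",
    "EdgeRecord",
    "kmer_profile",
    "d2star",
    "predict_hosts",
    "filter_edges",
]

#: Report a host prediction only below this d2* (strict).
REPORT_THRESHOLD = 0.4
#: Higher-confidence tier below this d2* (strict).
HIGH_CONF_THRESHOLD = 0.2

_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G


@dataclass
class KmerProfile:
    """Observed and Markov-expected k-mer counts of one genome.

    Counts are accumulated over both strands of every record; windows
    containing non-ACGT characters are skipped.  ``expected`` comes from
    the order-m Markov chain fit to the same sequence with pseudocount 1,
    so every entry is strictly positive; ``centered`` is observed - expected.
    """

    sequence_id: str
    k: int
    m: int
    observed: np.ndarray  # length 4^k
    expected: np.ndarray
    length: int  # total ungapped length over records

    @property
    def centered(self) -> np.ndarray:
        return self.observed - self.expected


@dataclass
class D2StarResult:
    virus_id: str
    host_id: str
    d2star: float
    tier: str  # "high" | "reported" | "none"


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    weight: float


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _count_words(codes: np.ndarray, k: int) -> np.ndarray:
    """Count k-words on one strand, skipping windows that contain non-ACGT."""
    L = len(codes)
    counts = np.zeros(4**k, dtype=np.int64)
    if L < k:
        return counts
    nw = L - k + 1
    bad = (codes == 4).astype(np.int32)
    bad_in_window = np.convolve(bad, np.ones(k, dtype=np.int32), mode="valid") > 0
    vals = codes[:nw].astype(np.int64).copy()
    for j in range(1, k):
        vals = vals * 4 + codes[j : j + nw]
    np.add.at(counts, vals[~bad_in_window], 1)
    return counts


def _both_strand_counts(seqs: list[str], k: int) -> np.ndarray:
    counts = np.zeros(4**k, dtype=np.int64)
    for s in seqs:
        codes = _encode(s)
        counts += _count_words(codes, k)
        counts += _count_words(_COMPLEMENT[codes[::-1]], k)
    return counts


def _word_digits(k: int) -> np.ndarray:
    """(4^k, k) base-4 digit expansion of every k-word index."""
    idx = np.arange(4**k)
    return np.stack([(idx // 4 ** (k - 1 - j)) % 4 for j in range(k)], axis=1)


def kmer_profile(seqs, sequence_id: str = "", k: int = 6, m: int = 2) -> KmerProfile:
    """Both-strand k-mer counts with order-m Markov expectations.

    Parameters
    ----------
    seqs : str, Bio.SeqRecord, or an iterable of either
        Genome sequence(s); multiple records (contigs/bins) are pooled.
    k : int
        Word size (default 6).
    m : int
        Markov order of the background chain, 0 <= m <= k-2 (default 2).
        Transition probabilities are estimated from the genome's own
        (m+1)-mer counts with pseudocount 1.
    """
    if isinstance(seqs, str) or hasattr(seqs, "seq"):
        seqs = [seqs]
    strings = [str(getattr(s, "seq", s)) for s in seqs]
    if not sequence_id:
        first = next(iter(seqs))
        sequence_id = getattr(first, "id", "")
    if not 0 <= m <= k - 2:
        raise ValueError(f"need 0 <= m <= k-2, got m={m}, k={k}")
    total_len = sum(len(s) for s in strings)
    if total_len < 1000:
        raise ValueError(
            f"total sequence length {total_len} < 1000: too short for stable "
            "k-mer statistics"
        )

    observed = _both_strand_counts(strings, k)
    total_words = int(observed.sum())
    if total_words == 0:
        raise ValueError("no valid k-mer windows (sequence all ambiguous?)")

    # order-m chain: initial distribution over m-words, transitions from
    # (m+1)-word counts; pseudocount 1 keeps every probability positive.
    c_m1 = _both_strand_counts(strings, m + 1).astype(float) + 1.0
    trans = c_m1.reshape(4**m, 4) if m > 0 else c_m1.reshape(1, 4)
    trans = trans / trans.sum(axis=1, keepdims=True)
    if m > 0:
        c_m = _both_strand_counts(strings, m).astype(float) + 1.0
        init = c_m / c_m.sum()
    else:
        init = np.ones(1)

    digits = _word_digits(k)
    if m > 0:
        pow4 = 4 ** np.arange(m - 1, -1, -1)
        ctx0 = digits[:, :m] @ pow4
        logp = np.log(init[ctx0])
        for i in range(m, k):
            ctx = digits[:, i - m : i] @ pow4
            logp += np.log(trans[ctx, digits[:, i]])
    else:
        logp = np.log(trans[0, digits[:, 0]])
        for i in range(1, k):
            logp += np.log(trans[0, digits[:, i]])
    expected = total_words * np.exp(logp)
    return KmerProfile(
        sequence_id=sequence_id, k=k, m=m, observed=observed,
        expected=expected, length=total_len,
    )


def d2star(x: KmerProfile, y: KmerProfile) -> float:
    """d2* dissimilarity in [0, 1] between two k-mer profiles.

    D2* = sum_w X~_w Y~_w / sqrt(E^x_w E^y_w) is a covariance-like score of
    the Markov-centered counts; d2* = (1 - D2* / (norm_x * norm_y)) / 2
    maps its cosine normalization onto [0, 1] (0 = identical composition).
    """
    if (x.k, x.m) != (y.k, y.m):
        raise ValueError("profiles must share k and Markov order")
    xc, yc = x.centered, y.centered
    denom = np.sqrt(x.expected * y.expected)
    num = float(np.sum(xc * yc / denom))
    nx = float(np.sqrt(np.sum(xc**2 / x.expected)))
    ny = float(np.sqrt(np.sum(yc**2 / y.expected)))
    if nx == 0 or ny == 0:
        raise ValueError("degenerate profile: centered counts are all zero")
    return float(min(max(0.5 * (1.0 - num / (nx * ny)), 0.0), 1.0))


def _tier(value: float, report: float, high: float) -> str:
    if value < high:
        return "high"
    if value < report:
        return "reported"
    return "none"


def predict_hosts(
    viruses: list[KmerProfile],
    hosts: list[KmerProfile],
    report_threshold: float = REPORT_THRESHOLD,
    high_conf_threshold: float = HIGH_CONF_THRESHOLD,
    full_matrix: bool = False,
):
    """For each virus, the host minimizing d2*, with its confidence tier.

    Tier is "none" when even the best host is at or above the reporting
    threshold ("below 0.4" is strict), "high" below the high-confidence
    threshold, otherwise "reported".  With ``full_matrix=True`` the whole
    virus x host d2* matrix is returned alongside the predictions.
    """
    if not hosts:
        raise ValueError("need at least one candidate host")
    M = np.array([[d2star(v, h) for h in hosts] for v in viruses])
    results = []
    for i, v in enumerate(viruses):
        j = int(np.argmin(M[i]))
        results.append(
            D2StarResult(
                virus_id=v.sequence_id,
                host_id=hosts[j].sequence_id,
                d2star=float(M[i, j]),
                tier=_tier(float(M[i, j]), report_threshold, high_conf_threshold),
            )
        )
    if full_matrix:
        mat = pd.DataFrame(
            M,
            index=[v.sequence_id for v in viruses],
            columns=[h.sequence_id for h in hosts],
        )
        return results, mat
    return results


def filter_edges(edges: list[EdgeRecord], cutoff: float = 0.4) -> list[EdgeRecord]:
    """Keep co-occurrence edges with |weight| >= cutoff, preserving order."""
    return [e for e in edges if abs(e.weight) >= cutoff]
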