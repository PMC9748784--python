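"""Synthetic data with known ground truth, for tests and demos.

Everything here is generated programmatically from a seed: length samples
drawn from known M1/M3/M4 parameterizations (for recovery experiments) and a
tiny GFF3 builder whose intron lengths are known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .m4 import M4Params, simulate_m4
from .simulator import IndelModelParams, SimulationConfig, simulate_stationary

__all__ = [
    "generate_m1_sample",
    "generate_m3_sample",
    "generate_m4_sample",
    "ToyTranscript",
    "ToyGene",
    "build_toy_gff3",
]


def generate_m1_sample(r: float, n: int, seed: int) -> np.ndarray:
    """``n`` i.i.d. draws from the exact M1 stationary law.

    The unit-indel stationary distribution is geometric on {0, 1, 2, ...}
    with success probability ``1 - r``, so no simulation is needed.
    """
    if not (0 <= r < 1):
        raise ValueError(f"r must lie in [0, 1), got {r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if r == 0:
        return np.zeros(n, dtype=np.int64)
    rng = np.random.default_rng(seed)
    return (rng.geometric(1.0 - r, size=n) - 1).astype(np.int64)


def generate_m3_sample(r: float, p_del: float, mu_i: float, mu_d: float,
                       n: int, seed: int, m_max: int = 150,
                       epsilon: float = 1e-6) -> np.ndarray:
    """Stationary M3 lengths at a known parameterization."""
    params = IndelModelParams.m3(r, p_del, mu_i, mu_d, m_max=m_max)
    cfg = SimulationConfig(n_replicates=n, seed=seed, epsilon=epsilon)
    return simulate_stationary(params, cfg).lengths


def generate_m4_sample(r: float, p_del: float, mu_i: float, mu_d: float,
                       le: float, li: float, pc: float, n: int, seed: int,
                       m_max: int = 150, epsilon: float = 1e-6) -> np.ndarray:
    """M4 mixture lengths at a known parameterization."""
    params = IndelModelParams.m3(r, p_del, mu_i, mu_d, m_max=m_max)
    cfg = SimulationConfig(n_replicates=n, seed=seed, epsilon=epsilon)
    return simulate_m4(params, M4Params(le=le, li=li, pc=pc), cfg).lengths


@dataclass
class ToyTranscript:
    transcript_id: str
    exons: List[Tuple[int, int]]          # 1-based inclusive (start, end)
    cds: Optional[List[Tuple[int, int]]] = None  # defaults to the exons


@dataclass
class ToyGene:
    gene_id: str
    transcripts: List[ToyTranscript]
    seqid: str = "chr1"
    strand: str = "+"


def _check_exons(tx: ToyTranscript) -> List[Tuple[int, int]]:
    exons = sorted(tx.exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise ValueError(
                f"overlapping exons in transcript {tx.transcript_id}: "
                f"({s1},{e1}) and ({s2},{e2})")
    for s, e in exons:
        if not (1 <= s <= e):
            raise ValueError(f"bad exon coordinates ({s},{e})")
    return exons


def build_toy_gff3(genes: Sequence[ToyGene]) -> str:
    """GFF3 text for a list of toy genes.

    Intron lengths of the returned annotation are known analytically:
    between consecutive exons ``[s1,e1]`` and ``[s2,e2]`` the intron has
    length ``s2 - e1 - 1``.
    """
    lines = ["##gff-version 3"]
    for gene in genes:
        all_exons = [ex for tx in gene.transcripts for ex in _check_exons(tx)]
        if not all_exons:
            raise ValueError(f"gene {gene.gene_id} has no exons")
        g_start = min(s for s, _ in all_exons)
        g_end = max(e for _, e in all_exons)
        lines.append("\t".join([
            gene.seqid, "toy", "gene", str(g_start), str(g_end), ".",
            gene.strand, ".", f"ID={gene.gene_id}"]))
        for tx in gene.transcripts:
            exons = _check_exons(tx)
            t_start, t_end = exons[0][0], exons[-1][1]
            lines.append("\t".join([
                gene.seqid, "toy", "mRNA", str(t_start), str(t_end), ".",
                gene.strand, ".",
                f"ID={tx.transcript_id};Parent={gene.gene_id}"]))
            for k, (s, e) in enumerate(exons, start=1):
                lines.append("\t".join([
                    gene.seqid, "toy", "exon", str(s), str(e), ".",
                    gene.strand, ".",
                    f"ID={tx.transcript_id}.exon{k};Parent={tx.transcript_id}"]))
            cds = tx.cds if tx.cds is not None else exons
            for k, (s, e) in enumerate(sorted(cds), start=1):
                lines.append("\t".join([
                    gene.seqid, "toy", "CDS", str(s), str(e), ".",
                    gene.strand, "0",
                    f"ID={tx.transcript_id}.cds{k};Parent={tx.transcript_id}"]))
    return "\n".join(lines) + "\n"
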