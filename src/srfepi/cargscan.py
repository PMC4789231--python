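"""Degenerate CArG-box (serum response element) scanning in promoter windows.

The serum response factor (SRF) binds the decamer consensus CC(A/T)6GG — the
CArG box.  Functional sites in vivo tolerate limited degeneracy, so the scanner
accepts 10-mers within a mismatch budget: at most ``max_total_mismatch``
mismatches overall, of which at most ``max_flank_mismatch`` may fall in the
CC/GG flanks (positions 1–2 and 9–10 of the motif); the six core positions
mismatch whenever the base is not A or T.

Hits are reported in TSS-relative, 1-based inclusive coordinates with no
position 0 (TSS = +1), negative upstream, in promoter orientation — the
convention used to label sites like "−309/−300".  Scanning the promoter strand
alone is complete because the acceptance class is closed under reverse
complement (flanks map to flanks, the A/T core to itself).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

MOTIF_LENGTH = 10
#: 0-based offsets of the CC / GG flanks and the A/T core within the decamer.
FLANK_OFFSETS = (0, 1, 8, 9)
CORE_OFFSETS = (2, 3, 4, 5, 6, 7)
_FLANK_EXPECTED = "CCGG"  # expected base at each flank offset, in order


@dataclass(frozen=True)
class CArGModel:
    """Mismatch budget for accepting a decamer as a CArG box."""

    max_total_mismatch: int = 2
    max_flank_mismatch: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.max_flank_mismatch <= self.max_total_mismatch):
            raise ValueError(
                "require 0 <= max_flank_mismatch <= max_total_mismatch, got "
                f"{self.max_flank_mismatch}/{self.max_total_mismatch}"
            )


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence covering TSS ± window in promoter orientation.

    The sequence has length 2*window: positions −window..−1 upstream, then
    +1..+window downstream (no position 0).
    """

    gene_id: str
    tss_position: int
    strand: str
    sequence: str
    window: int = 10000

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.sequence) != 2 * self.window:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"2*window = {2 * self.window}"
            )
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.gene_id}: non-ACGTN characters {bad}")

    def index_to_tss(self, i: int) -> int:
        """TSS-relative position of sequence index ``i`` (no position 0)."""
        return i - self.window if i < self.window else i - self.window + 1

    def tss_to_index(self, pos: int) -> int:
        if pos == 0:
            raise ValueError("there is no TSS-relative position 0")
        return pos + self.window if pos < 0 else pos + self.window - 1


@dataclass(frozen=True)
class ConservedBlock:
    """A mouse–human conserved noncoding block, TSS-relative inclusive coords."""

    gene_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"block start {self.start} >= end {self.end}")


@dataclass
class MotifHit:
    gene_id: str
    start: int  # TSS-relative, 1-based inclusive, strand-oriented
    end: int
    sequence: str
    mismatch_total: int
    mismatch_flank: int
    in_conserved: bool = False


def mismatch_profile(tenmer: str, model: CArGModel | None = None) -> tuple[int, int, int]:
    """(total, flank, core) mismatch counts of a decamer against CC(A/T)6GG.

    N (or any non-ACGT base) counts as a mismatch at its position.
    """
    if len(tenmer) != MOTIF_LENGTH:
        raise ValueError(f"expected a 10-mer, got length {len(tenmer)}")
    s = tenmer.upper()
    flank = sum(s[off] != exp for off, exp in zip(FLANK_OFFSETS, _FLANK_EXPECTED))
    core = sum(s[off] not in "AT" for off in CORE_OFFSETS)
    return flank + core, flank, core


def is_carg(tenmer: str, model: CArGModel | None = None) -> bool:
    """Accept a decamer iff total and flank mismatches are within budget."""
    model = model or CArGModel()
    total, flank, _ = mismatch_profile(tenmer)
    return total <= model.max_total_mismatch and flank <= model.max_flank_mismatch


_BASE_CODE = np.full(256, 4, dtype=np.int8)  # 4 = anything else (N etc.)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(sequence: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_mismatches(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-start-index (flank, core) mismatch counts for all decamer windows."""
    n = codes.size - MOTIF_LENGTH + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z
    not_c = codes != 1
    not_g = codes != 2
    not_at = (codes != 0) & (codes != 3)
    flank = (
        not_c[0:n].astype(np.int64)
        + not_c[1 : n + 1]
        + not_g[8 : n + 8]
        + not_g[9 : n + 9]
    )
    cs = np.concatenate(([0], np.cumsum(not_at.astype(np.int64))))
    core = cs[8 : n + 8] - cs[2 : n + 2]
    return flank, core


def scan_sequence(sequence: str, model: CArGModel | None = None) -> np.ndarray:
    """0-based start indices of all accepted decamer windows in ``sequence``."""
    model = model or CArGModel()
    flank, core = _window_mismatches(_encode(sequence))
    ok = (flank <= model.max_flank_mismatch) & (
        flank + core <= model.max_total_mismatch
    )
    return np.flatnonzero(ok)


def scan_promoter(rec: PromoterRecord, model: CArGModel | None = None) -> list[MotifHit]:
    """All accepted CArG decamers in a promoter, overlapping windows included."""
    model = model or CArGModel()
    hits = []
    for i in map(int, scan_sequence(rec.sequence, model)):
        tenmer = rec.sequence[i : i + MOTIF_LENGTH].upper()
        total, flank, _ = mismatch_profile(tenmer)
        hits.append(
            MotifHit(
                gene_id=rec.gene_id,
                start=rec.index_to_tss(i),
                end=rec.index_to_tss(i + MOTIF_LENGTH - 1),
                sequence=tenmer,
                mismatch_total=total,
                mismatch_flank=flank,
            )
        )
    return hits


def flag_conserved(
    hits: Iterable[MotifHit], blocks: Iterable[ConservedBlock]
) -> list[MotifHit]:
    """Mark hits wholly contained in a conserved block of the same gene."""
    by_gene: dict[str, list[ConservedBlock]] = {}
    for b in blocks:
        by_gene.setdefault(b.gene_id, []).append(b)
    out = []
    for h in hits:
        contained = any(
            b.start <= h.start and h.end <= b.end for b in by_gene.get(h.gene_id, ())
        )
        out.append(replace(h, in_conserved=contained))
    return out


def summarize_genes(
    hits: Iterable[MotifHit],
    min_sites: int = 2,
    conserved_only: bool = True,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene site counts and the >=min_sites selection flag.

    Genes listed in ``gene_ids`` but without hits appear with zero counts.
    """
    rows: dict[str, list[int]] = {g: [0, 0] for g in (gene_ids or [])}
    for h in hits:
        rows.setdefault(h.gene_id, [0, 0])
        rows[h.gene_id][0] += 1
        rows[h.gene_id][1] += int(h.in_conserved)
    df = pd.DataFrame(
        [(g, n, c) for g, (n, c) in sorted(rows.items())],
        columns=["gene_id", "n_sites", "n_conserved_sites"],
    )
    counted = df["n_conserved_sites"] if conserved_only else df["n_sites"]
    df["passes_min_sites"] = counted >= min_sites
    return df


@dataclass(frozen=True)
class EnrichmentResult:
    fold_enrichment: float
    p_hypergeom: float
    p_permutation: float
    n_foreground: int
    n_foreground_with_feature: int
    n_background: int
    n_background_with_feature: int
    undefined: bool = False


def enrichment_test(
    foreground_genes: Sequence[str],
    background_genes: Sequence[str],
    has_feature: Mapping[str, bool] | set,
    n_permutations: int = 10000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Overrepresentation of a promoter feature in a gene set.

    Fold enrichment is the ratio of feature proportions (foreground over
    background); significance is the upper-tail hypergeometric probability and
    an empirical tail over random same-size draws from the background.
    """
    fg = list(dict.fromkeys(foreground_genes))
    bg = list(dict.fromkeys(background_genes))
    missing = set(fg) - set(bg)
    if missing:
        raise ValueError(f"foreground genes not in background: {sorted(missing)[:5]}")
    if not fg:
        raise ValueError("foreground is empty")
    feat = (
        has_feature
        if isinstance(has_feature, (set, frozenset))
        else {g for g, v in has_feature.items() if v}
    )
    flags = np.array([g in feat for g in bg])
    n, M = len(fg), len(bg)
    K = int(flags.sum())
    k = sum(g in feat for g in fg)
    undefined = K == 0
    fold = float("nan") if undefined else (k / n) / (K / M)
    p_hyper = float(hypergeom.sf(k - 1, M, K, n))
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    hits = 0
    for _ in range(n_permutations):
        draw = rng.choice(M, size=n, replace=False)
        if int(flags[draw].sum()) >= k:
            hits += 1
    p_perm = (hits + 1) / (n_permutations + 1)
    return EnrichmentResult(
        fold_enrichment=fold,
        p_hypergeom=p_hyper,
        p_permutation=p_perm,
        n_foreground=n,
        n_foreground_with_feature=k,
        n_background=M,
        n_background_with_feature=K,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# IO: FASTA promoters (header `gene|tss|strand`), BED blocks, TSV tables
# ---------------------------------------------------------------------------


def read_promoters(path: str | Path, window: int = 10000) -> list[PromoterRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            gene_id, tss, strand = rec.id.split("|")
        except ValueError as exc:
            raise ValueError(
                f"FASTA header {rec.id!r} is not of the form gene|tss|strand"
            ) from exc
        records.append(
            PromoterRecord(
                gene_id=gene_id,
                tss_position=int(tss),
                strand=strand,
                sequence=str(rec.seq),
                window=window,
            )
        )
    return records


def write_promoters(records: Iterable[PromoterRecord], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    out = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.gene_id}|{r.tss_position}|{r.strand}",
            description="",
        )
        for r in records
    ]
    seqio_write(out, str(path), "fasta")


def read_blocks_bed(
    path: str | Path, promoters: Mapping[str, PromoterRecord]
) -> list[ConservedBlock]:
    """Read conserved blocks from BED (0-based half-open, sequence coords).

    The BED chrom field names the gene; intervals are converted to TSS-relative
    inclusive coordinates via the gene's promoter record.
    """
    blocks = []
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["gene", "start", "end"]
    )
    for gene, s, e in df.itertuples(index=False):
        rec = promoters[gene]
        blocks.append(
            ConservedBlock(
                gene_id=gene,
                start=rec.index_to_tss(int(s)),
                end=rec.index_to_tss(int(e) - 1),
            )
        )
    return blocks


def write_blocks_bed(
    blocks: Iterable[ConservedBlock],
    promoters: Mapping[str, PromoterRecord],
    path: str | Path,
) -> None:
    rows = []
    for b in blocks:
        rec = promoters[b.gene_id]
        rows.append((b.gene_id, rec.tss_to_index(b.start), rec.tss_to_index(b.end) + 1))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.gene_id, h.start, h.end, h.sequence, h.mismatch_total, h.mismatch_flank, h.in_conserved)
            for h in hits
        ],
        columns=[
            "gene_id",
            "start",
            "end",
            "sequence",
            "mismatch_total",
            "mismatch_flank",
            "in_conserved",
        ],
    )
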