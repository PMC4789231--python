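"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions of a 2x2 (CTR/KO genotype x
saline/KA treatment) design: a probe-intensity matrix with planted
interaction genes (induced by KA in CTR only), promoter sequences with
planted CArG boxes inside or outside conserved noncoding blocks, per-animal
EEG amplitude envelopes with planted seizure discharges, and qPCR / ChIP-qPCR
Ct tables constructed by inverting the ddCT and percent-of-input formulas so
the configured fold changes and enrichments are recovered exactly in the
noise-free case.

Everything is deterministic under a fixed seed: each generator draws from its
own child stream of the configured seed, so stages can be regenerated
independently without disturbing one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .cargscan import (
    CArGModel,
    ConservedBlock,
    MOTIF_LENGTH,
    PromoterRecord,
    scan_sequence,
)
from .eeg import EnvelopeRecording
from .expression import ExpressionMatrix

_DECODE = np.array(list("ACGT"))

# child-stream tags so each generator has an independent substream of the seed
_STREAM_EXPRESSION = 1
_STREAM_PROMOTERS = 2
_STREAM_EEG = 3
_STREAM_CT = 4


@dataclass
class CtParams:
    """Targets and constants for the qPCR / ChIP Ct-table generators."""

    reference_ct: float = 18.0
    base_target_ct: float = 24.0
    n_replicates: int = 3
    ct_noise_sd: float = 0.0
    #: linear KA/saline induction per gene in CTR animals
    fold_ka_ctr: Mapping[str, float] = field(
        default_factory=lambda: {"Fos": 8.0, "Npas4": 6.0, "Gadd45g": 4.0, "Zfp36": 4.0}
    )
    #: same induction in KO animals (blunted by default)
    fold_ka_ko: Mapping[str, float] = field(default_factory=dict)
    input_fraction: float = 0.1
    chip_input_ct: float = 22.0
    chip_background_percent: float = 0.1
    #: SRF-over-background enrichment per amplicon and condition (naive / KA)
    chip_enrichment: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "Fos": {"naive": 5.0, "KA": 5.0},
            "Npas4": {"naive": 1.0, "KA": 5.0},
            "Gadd45g": {"naive": 1.0, "KA": 5.0},
            "Zfp36": {"naive": 1.0, "KA": 5.0},
            "Syt4": {"naive": 1.0, "KA": 1.0},
        }
    )


@dataclass
class SimConfig:
    """Study conditions for all generators (defaults mirror the experiments)."""

    seed: int = 0
    # expression: 2x2 design, 5-6 biological replicates per cell
    n_per_group: int = 6
    n_per_cell: Mapping[str, int] | None = None  # e.g. {"CTR_saline": 5}
    n_probes: int = 5000
    n_planted_up: int = 216
    n_planted_down: int = 162
    planted_log2_effect: float = 2.0
    residual_sd: float = 0.1
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.309  # uniform half-width = sqrt(3)*sd, range ~4..12
    # promoters
    promoter_count: int = 12
    promoter_halfwidth: int = 10000
    planted_sites_per_gene: int = 2
    conserved_block_fraction: float = 0.2
    planted_conserved_fraction: float = 1.0
    # EEG (18 days of 1-s envelope samples per animal)
    n_animals: int = 6
    eeg_days: float = 18.0
    eeg_sample_interval: float = 1.0
    baseline_amplitude: float = 1.0
    eeg_noise_shape: float = 4.0  # Nakagami m; m=1 is Rayleigh
    seizure_rate_per_day: float = 3.13
    seizure_duration_mean: float = 35.7
    seizure_duration_sd: float = 10.0
    seizure_min_duration: float = 5.0
    seizure_amplitude_ratio: float = 3.0
    latency_offset_h: float = 24.0
    first_latency_mean_h: float | None = None
    first_latency_sd_h: float = 12.0
    # qPCR / ChIP
    ct_params: CtParams = field(default_factory=CtParams)

    def __post_init__(self) -> None:
        counts = (
            self.n_probes,
            self.n_planted_up,
            self.n_planted_down,
            self.promoter_count,
            self.planted_sites_per_gene,
            self.n_animals,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be nonnegative")
        if self.n_planted_up + self.n_planted_down > self.n_probes:
            raise ValueError("more planted probes than probes")
        if not 0.0 <= self.conserved_block_fraction <= 1.0:
            raise ValueError("conserved_block_fraction must lie in [0, 1]")
        if self.seizure_amplitude_ratio <= 2.0:
            raise ValueError("seizure_amplitude_ratio must exceed 2")
        if self.promoter_halfwidth < MOTIF_LENGTH:
            raise ValueError("promoter_halfwidth shorter than the motif")
        if self.residual_sd < 0 or self.baseline_log2_sd < 0:
            raise ValueError("standard deviations must be nonnegative")

    def cell_sizes(self) -> dict[str, int]:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        sizes = {
            f"{g}_{t}": self.n_per_group
            for g in ("CTR", "KO")
            for t in ("saline", "KA")
        }
        for key, n in (self.n_per_cell or {}).items():
            if key not in sizes:
                raise ValueError(f"unknown design cell {key!r}")
            if n <= 0:
                raise ValueError("per-cell n must be positive")
            sizes[key] = n
        return sizes


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSim:
    matrix: ExpressionMatrix  # linear intensities
    sample_sheet: pd.DataFrame
    truth: pd.Series  # per probe: none / up / down
    probe_gene_map: pd.Series  # probe_id -> gene_id (one gene per probe)


def simulate_expression(config: SimConfig) -> ExpressionSim:
    """Probe intensities with planted genotype x treatment interaction genes.

    Planted "up" probes gain ``planted_log2_effect`` mean log2 intensity in
    the CTR-KA cell only (KA induction requiring SRF); "down" probes lose the
    same amount there.  All other cell means equal the probe baseline, with
    i.i.d. Gaussian log2 noise of sd ``residual_sd``.

    Per-probe baselines are uniform on the log2 scale over
    mean +/- sqrt(3)*sd (default ~4..12, the array's usable dynamic range).
    The flat density keeps quantile spacing constant, so quantile
    normalization neither creates rank-shift artifacts in sparse tails nor
    collapses planted effects; planted baselines are drawn away from the
    range edges so induction/repression stays on-scale (no saturation).
    """
    rng = _rng(config, _STREAM_EXPRESSION)
    sizes = config.cell_sizes()
    sample_rows = []
    for cell, n in sizes.items():
        genotype, treatment = cell.split("_")
        for i in range(n):
            sample_rows.append((f"{cell}_{i + 1}", genotype, treatment))
    sheet = pd.DataFrame(sample_rows, columns=["sample_id", "genotype", "treatment"])

    p = config.n_probes
    probe_ids = pd.Index([f"probe_{i + 1:05d}" for i in range(p)], name="probe_id")
    gene_ids = pd.Series(
        [f"gene_{i + 1:05d}" for i in range(p)], index=probe_ids, name="gene_id"
    )

    order = rng.permutation(p)
    up_idx = order[: config.n_planted_up]
    down_idx = order[config.n_planted_up : config.n_planted_up + config.n_planted_down]
    truth = pd.Series("none", index=probe_ids, name="truth")
    truth.iloc[up_idx] = "up"
    truth.iloc[down_idx] = "down"

    half = np.sqrt(3.0) * config.baseline_log2_sd
    lo, hi = config.baseline_log2_mean - half, config.baseline_log2_mean + half
    baseline = rng.uniform(lo, hi, size=p)
    eff = config.planted_log2_effect
    margin = 0.5  # keep planted effects off the dynamic-range edges
    if eff > 0 and config.n_planted_up + config.n_planted_down > 0:
        if hi - lo <= eff + margin:
            raise ValueError("dynamic range too narrow for the planted effect")
        baseline[up_idx] = rng.uniform(lo, hi - eff - margin, size=up_idx.size)
        baseline[down_idx] = rng.uniform(lo + eff + margin, hi, size=down_idx.size)
    effect = np.zeros(p)
    effect[up_idx] = eff
    effect[down_idx] = -eff

    columns = {}
    for _, (sample_id, genotype, treatment) in sheet.iterrows():
        mean = baseline.copy()
        if genotype == "CTR" and treatment == "KA":
            mean = mean + effect
        noise = (
            rng.normal(0.0, config.residual_sd, size=p)
            if config.residual_sd > 0
            else 0.0
        )
        columns[sample_id] = mean + noise
    log2 = pd.DataFrame(columns, index=probe_ids)
    matrix = ExpressionMatrix(2.0 ** log2, scale="linear")
    return ExpressionSim(
        matrix=matrix, sample_sheet=sheet, truth=truth, probe_gene_map=gene_ids
    )


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


@dataclass
class PromoterSim:
    records: list[PromoterRecord]
    blocks: list[ConservedBlock]
    truth: pd.DataFrame  # gene_id, start, end, sequence, conserved


def _random_consensus(rng: np.random.Generator) -> str:
    core = "".join(rng.choice(["A", "T"], size=6))
    return f"CC{core}GG"


def _place_blocks(
    length: int, fraction: float, rng: np.random.Generator, block_len: int = 500
) -> list[tuple[int, int]]:
    """Non-overlapping [start, stop) intervals covering ~fraction of length."""
    if fraction <= 0:
        return []
    n_blocks = max(1, round(fraction * length / block_len))
    intervals: list[tuple[int, int]] = []
    for _ in range(n_blocks):
        for _attempt in range(1000):
            s = int(rng.integers(0, length - block_len))
            if all(s + block_len <= bs or s >= be for bs, be in intervals):
                intervals.append((s, s + block_len))
                break
        else:
            raise RuntimeError("could not place conserved blocks without overlap")
    return sorted(intervals)


def _site_positions(
    length: int,
    n_sites: int,
    conserved_flags: Sequence[bool],
    blocks: list[tuple[int, int]],
    rng: np.random.Generator,
) -> list[int]:
    """Start indices for planted decamers, wholly inside/outside blocks."""
    inside = [(s, e) for s, e in blocks if e - s >= MOTIF_LENGTH]
    occupied: list[tuple[int, int]] = []

    def free(s: int) -> bool:
        return all(s + MOTIF_LENGTH <= os or s >= oe for os, oe in occupied)

    positions = []
    for want_conserved in conserved_flags:
        for _attempt in range(5000):
            if want_conserved:
                if not inside:
                    raise ValueError("no conserved block can hold a planted site")
                bs, be = inside[int(rng.integers(len(inside)))]
                s = int(rng.integers(bs, be - MOTIF_LENGTH + 1))
            else:
                s = int(rng.integers(0, length - MOTIF_LENGTH + 1))
                if any(s + MOTIF_LENGTH > bs and s < be for bs, be in blocks):
                    continue
            if free(s):
                occupied.append((s, s + MOTIF_LENGTH))
                positions.append(s)
                break
        else:
            raise RuntimeError("could not place planted sites without overlap")
    return positions


def build_promoter(
    gene_id: str,
    window: int,
    planted: Sequence[tuple[int, str]],
    rng: np.random.Generator,
    model: CArGModel | None = None,
    max_passes: int = 200,
) -> PromoterRecord:
    """Uniform-random promoter with the given decamers planted at seq indices.

    Background letters are rejection-resampled until the scanner finds
    exactly the planted sites and nothing else.
    """
    model = model or CArGModel()
    length = 2 * window
    codes = rng.integers(0, 4, size=length)
    protected = np.zeros(length, dtype=bool)
    planted_starts = set()
    for start, tenmer in planted:
        if start < 0 or start + MOTIF_LENGTH > length:
            raise ValueError(f"planted site at {start} extends past sequence bounds")
        codes[start : start + MOTIF_LENGTH] = [
            "ACGT".index(b) for b in tenmer.upper()
        ]
        protected[start : start + MOTIF_LENGTH] = True
        planted_starts.add(start)

    for _ in range(max_passes):
        seq = "".join(_DECODE[codes])
        offending = [
            int(i) for i in scan_sequence(seq, model) if int(i) not in planted_starts
        ]
        if not offending:
            return PromoterRecord(
                gene_id=gene_id, tss_position=0, strand="+", sequence=seq, window=window
            )
        for i in offending:
            span = slice(i, i + MOTIF_LENGTH)
            redraw = np.flatnonzero(~protected[span]) + i
            if redraw.size == 0:
                continue  # coincides with a planted site; cannot touch
            codes[redraw] = rng.integers(0, 4, size=redraw.size)
    raise RuntimeError("background resampling did not converge")


def simulate_promoters(
    config: SimConfig,
    model: CArGModel | None = None,
    gene_ids: Sequence[str] | None = None,
) -> PromoterSim:
    """Promoters with planted consensus CArG boxes and conserved blocks."""
    model = model or CArGModel()
    rng = _rng(config, _STREAM_PROMOTERS)
    length = 2 * config.promoter_halfwidth
    if gene_ids is None:
        gene_ids = [f"gene_{g + 1:05d}" for g in range(config.promoter_count)]
    records, all_blocks, truth_rows = [], [], []
    for gene_id in gene_ids:
        block_idx = _place_blocks(length, config.conserved_block_fraction, rng)
        flags = [
            bool(rng.random() < config.planted_conserved_fraction)
            if config.conserved_block_fraction > 0
            else False
            for _ in range(config.planted_sites_per_gene)
        ]
        positions = _site_positions(
            length, config.planted_sites_per_gene, flags, block_idx, rng
        )
        planted = [(pos, _random_consensus(rng)) for pos in positions]
        rec = build_promoter(gene_id, config.promoter_halfwidth, planted, rng, model)
        records.append(rec)
        for (bs, be) in block_idx:
            all_blocks.append(
                ConservedBlock(
                    gene_id=gene_id,
                    start=rec.index_to_tss(bs),
                    end=rec.index_to_tss(be - 1),
                )
            )
        for (pos, tenmer), conserved in zip(planted, flags):
            truth_rows.append(
                (
                    gene_id,
                    rec.index_to_tss(pos),
                    rec.index_to_tss(pos + MOTIF_LENGTH - 1),
                    tenmer,
                    conserved,
                )
            )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "start", "end", "sequence", "conserved"]
    )
    return PromoterSim(records=records, blocks=all_blocks, truth=truth)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


@dataclass
class EegSim:
    recordings: list[EnvelopeRecording]
    truth: dict[str, pd.DataFrame]  # animal_id -> planted events (start/end s)


def _nakagami_noise(
    rng: np.random.Generator, m: float, median: float, size: int
) -> np.ndarray:
    """Nakagami-m envelope noise scaled so its median equals ``median``."""
    gamma_median = float(gamma_dist.ppf(0.5, m))
    omega = median * median / gamma_median * m
    return np.sqrt(rng.gamma(shape=m, scale=omega / m, size=size))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[draw > lower]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def simulate_eeg(config: SimConfig, group: str = "KO") -> EegSim:
    """Per-animal envelope recordings with planted spontaneous discharges.

    ``seizure_rate_per_day`` is the expected number of detected seizures per
    *recording* day (the frequency metric's denominator), so events are
    Poisson-placed in the post-latency window with a correspondingly higher
    intensity.  When ``first_latency_mean_h`` is set, each animal's first
    event time is drawn from a truncated normal and later events follow the
    Poisson process after it.  Planted durations are truncated above the
    detector minimum and aligned to the envelope sample grid, so every planted
    event satisfies the detection rule by construction.
    """
    dt = config.eeg_sample_interval
    total_s = config.eeg_days * 86400.0
    n_samples = int(round(total_s / dt))
    offset_s = config.latency_offset_h * 3600.0
    rate_total = config.seizure_rate_per_day * config.eeg_days
    if rate_total > 0:
        if offset_s >= total_s:
            raise ValueError("latency offset leaves no spontaneous window")
        if rate_total * config.seizure_duration_mean > 0.5 * (total_s - offset_s):
            raise ValueError("seizure rate too high: events cannot avoid overlap")

    min_samples = int(np.floor(config.seizure_min_duration / dt)) + 1
    recordings, truths = [], {}
    for k in range(config.n_animals):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _STREAM_EEG, k])
        )
        animal_id = f"{group}_{k + 1}"
        starts_s: list[float] = []
        if rate_total > 0:
            if config.first_latency_mean_h is not None:
                if rate_total < 1:
                    raise ValueError(
                        "explicit first-event latency needs rate*days >= 1"
                    )
                t1 = float(
                    _truncated_normal(
                        rng,
                        config.first_latency_mean_h * 3600.0,
                        config.first_latency_sd_h * 3600.0,
                        offset_s,
                        1,
                    )[0]
                )
                t1 = min(t1, total_s - config.seizure_duration_mean)
                starts_s.append(t1)
                residual = rate_total - 1.0
                span = total_s - t1
                n_more = rng.poisson(residual) if residual > 0 else 0
                starts_s.extend((t1 + rng.random(n_more) * span).tolist())
            else:
                n_events = rng.poisson(rate_total)
                span = total_s - offset_s
                starts_s.extend((offset_s + rng.random(n_events) * span).tolist())
        durations = _truncated_normal(
            rng,
            config.seizure_duration_mean,
            config.seizure_duration_sd,
            config.seizure_min_duration,
            len(starts_s),
        )

        envelope = _nakagami_noise(
            rng, config.eeg_noise_shape, config.baseline_amplitude, n_samples
        )
        placed: list[tuple[int, int]] = []  # sample-index intervals
        for s_time, dur in sorted(zip(starts_s, durations)):
            n_ev = max(min_samples, int(round(dur / dt)))
            si = int(round(s_time / dt))
            si = min(max(si, 0), n_samples - n_ev)
            # keep >= 2 clean samples between events so runs never merge
            if any(si < pe + 2 and si + n_ev + 2 > ps for ps, pe in placed):
                continue
            placed.append((si, si + n_ev))
            amp = config.seizure_amplitude_ratio * config.baseline_amplitude
            envelope[si : si + n_ev] = amp * (1.0 + 0.2 * rng.random(n_ev))
        placed.sort()
        truths[animal_id] = pd.DataFrame(
            [(ps * dt, pe * dt, (pe - ps) * dt) for ps, pe in placed],
            columns=["start_s", "end_s", "duration_s"],
        )
        recordings.append(
            EnvelopeRecording(
                animal_id=animal_id,
                group=group,
                sample_interval=dt,
                envelope=envelope,
            )
        )
    return EegSim(recordings=recordings, truth=truths)


# ---------------------------------------------------------------------------
# qPCR / ChIP Ct tables
# ---------------------------------------------------------------------------


@dataclass
class CtSim:
    ct_table: pd.DataFrame
    chip_table: pd.DataFrame
    fold_truth: pd.DataFrame  # gene, condition-pair fold changes
    binding_truth: pd.DataFrame  # amplicon, condition, bound


def simulate_ct_tables(config: SimConfig) -> CtSim:
    """Ct tables built by inverting ddCT and percent-of-input.

    With zero Ct noise the ddCT fold change of KA over saline equals the
    configured fold exactly, and the ChIP binding call reproduces the planted
    enrichment pattern (SRF percent-of-input = background x enrichment, with
    IgG and the Arbp-exon amplicon at background).
    """
    p = config.ct_params
    rng = _rng(config, _STREAM_CT)
    noise = lambda: rng.normal(0.0, p.ct_noise_sd) if p.ct_noise_sd > 0 else 0.0

    ct_rows = []
    fold_rows = []
    for gene, fold_ctr in p.fold_ka_ctr.items():
        fold_ko = dict(p.fold_ka_ko).get(gene, 1.0)
        rel = {
            "CTR_saline": 1.0,
            "CTR_KA": fold_ctr,
            "KO_saline": 1.0,
            "KO_KA": fold_ko,
        }
        for condition, expr in rel.items():
            for r in range(p.n_replicates):
                ct_rows.append(
                    (
                        f"{condition}_{r + 1}",
                        condition,
                        gene,
                        p.base_target_ct - np.log2(expr) + noise(),
                        p.reference_ct + noise(),
                    )
                )
        fold_rows.append((gene, fold_ctr, fold_ko))
    ct_table = pd.DataFrame(
        ct_rows,
        columns=["sample_id", "condition", "target_gene", "ct_target", "ct_reference"],
    )
    fold_truth = pd.DataFrame(
        fold_rows, columns=["gene", "fold_ka_ctr", "fold_ka_ko"]
    )

    def ct_ip_for(percent: float) -> float:
        return p.chip_input_ct - np.log2(percent / (100.0 * p.input_fraction))

    chip_rows = []
    bind_rows = []
    amplicons = dict(p.chip_enrichment)
    for amplicon, by_cond in amplicons.items():
        for condition in ("naive", "KA"):
            enrich = dict(by_cond).get(condition, 1.0)
            pct_srf = p.chip_background_percent * enrich
            for antibody, pct in (("SRF", pct_srf), ("IgG", p.chip_background_percent)):
                for _r in range(p.n_replicates):
                    chip_rows.append(
                        (
                            antibody,
                            amplicon,
                            condition,
                            ct_ip_for(pct) + noise(),
                            p.chip_input_ct + noise(),
                            p.input_fraction,
                        )
                    )
            bind_rows.append((amplicon, condition, enrich > 2.0))
    for condition in ("naive", "KA"):
        for antibody in ("SRF", "IgG"):
            for _r in range(p.n_replicates):
                chip_rows.append(
                    (
                        antibody,
                        "Arbp exon",
                        condition,
                        ct_ip_for(p.chip_background_percent) + noise(),
                        p.chip_input_ct + noise(),
                        p.input_fraction,
                    )
                )
    chip_table = pd.DataFrame(
        chip_rows,
        columns=["antibody", "amplicon_id", "condition", "ct_ip", "ct_input", "input_fraction"],
    )
    binding_truth = pd.DataFrame(
        bind_rows, columns=["amplicon_id", "condition", "bound"]
    )
    return CtSim(
        ct_table=ct_table,
        chip_table=chip_table,
        fold_truth=fold_truth,
        binding_truth=binding_truth,
    )
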