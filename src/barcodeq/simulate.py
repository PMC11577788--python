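"""Ground-truthed synthetic data for every pipeline stage.

Generators emulate the study conditions of a barcoded-library competition
on epithelial monolayers: ~equal (1:1:...:1) nine-strain mixtures tagged at
the *cat* locus, 150-bp paired-end amplicon sequencing with 6-base
diversity spacers, per-base substitution error tied to the Phred quality
profile, a strain-specific adhesion effect in washed wells (unwashed wells
are sampling-only controls), fecal CFU time courses with a detection
limit, and logistic growth curves. Every generator is a pure function of
its configuration, seed included, and returns the generating truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import DNA_BASES, check_dna, revcomp
from .barcode_model import (
    BARCODE_LENGTH,
    CODON_SLICE,
    BarcodeTemplate,
    instantiate_oligo,
)
from .codon import STANDARD_TABLE, CodonTable
from .competition import CFUSeries, GrowthCurve
from .demux import PHRED_OFFSET, ReadPair

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

# Constant amplicon pads standing in for the invariant cat sequence either
# side of the 80-nt repair-oligo region (exact enrichment-primer coordinates
# are internal to cat; 50 nt each side is representative).
PAD_LEFT = "ATGGAGAAAAAGATCACTGGTTATACCACCGTTGATATATCCCAATGGCA"
PAD_RIGHT = "CGGTGAGCTGGTGATATGGGATAGTGTTCACCCTTGTTACACCGTTTTCC"


@dataclass(frozen=True)
class SimConfig:
    """Conditions for the simulated competition experiment.

    Proportions are the input-mixture composition (default nine strains at
    ~1:1), ``effects`` the per-strain shift in percentage points applied to
    washed-well TF proportions before renormalisation (the adhesion
    signal), and the two coefficients of variation the technical- and
    biological-replicate noise on proportions (logistic-normal).
    """

    seed: int = 0
    n_strains: int = 9
    true_proportions_t0: tuple[float, ...] | None = None  # default uniform
    effects: Mapping[str, float] = field(default_factory=lambda: {"dcmbA": -2.5})
    n_experiments: int = 3
    n_technical: int = 3
    read_depth: int = 100_000
    read_length: int = 150
    spacer_len: int = 6
    per_base_error_rate: float | None = None
    q_mid: int = 35
    q_tail: int = 25
    tail_len: int = 10
    technical_cv: float = 0.05
    biological_cv: float = 0.05
    position_bias: np.ndarray | None = None
    moi: float = 5.0  # metadata only
    # CFU clearance time course
    clearance_slope: float = 0.8  # log10 CFU per day
    clearance_noise_sd: float = 0.2
    n_subjects: int = 6
    days: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    log10_cfu0: float = 8.0
    lod: float = 100.0  # CFU per 100 mg
    # growth curves
    growth_rate: float = 1.0  # doublings per hour
    growth_lag_h: float = 1.0
    od0: float = 0.02
    od_capacity: float = 2.0
    growth_noise_cv: float = 0.02

    def proportions(self) -> np.ndarray:
        p = (
            np.full(self.n_strains, 1.0 / self.n_strains)
            if self.true_proportions_t0 is None
            else np.asarray(self.true_proportions_t0, dtype=float)
        )
        if p.size != self.n_strains:
            raise ValueError("proportions length must equal n_strains")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("proportions must be nonnegative and sum to 1")
        return p

    def __post_init__(self) -> None:
        if self.per_base_error_rate is not None and not (
            0.0 <= self.per_base_error_rate <= 1.0
        ):
            raise ValueError("per_base_error_rate must lie in [0, 1]")
        self.proportions()


def gen_cds_fixture(
    n_codons: int, seed: int = 0, table: CodonTable = STANDARD_TABLE
) -> str:
    """A random valid CDS: start codon, ``n_codons`` sense codons total, stop.

    Length is ``3 * (n_codons + 1)`` nt including the terminal stop.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    rng = np.random.default_rng(seed)
    sense = sorted(table.sense_codons)
    body = [sense[i] for i in rng.integers(0, len(sense), n_codons - 1)]
    return "ATG" + "".join(body) + "TAA"


def gen_barcode_set(
    n: int,
    template: BarcodeTemplate,
    bias: np.ndarray | None = None,
    seed: int = 0,
    table: CodonTable = STANDARD_TABLE,
) -> tuple[list[str], pd.DataFrame]:
    """Sample ``n`` functional barcodes (rejecting stop replacements).

    ``bias`` is an optional 6x4 row-stochastic base-weight matrix over
    A/C/G/T per position (e.g. A-enriched wobble positions). Returns the
    barcodes plus a truth table with each barcode's replacement amino acid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if bias is None:
        w = np.full((BARCODE_LENGTH, 4), 0.25)
    else:
        w = np.asarray(bias, dtype=float)
        if w.shape != (BARCODE_LENGTH, 4) or np.any(w < 0):
            raise ValueError("bias must be a nonnegative 6x4 matrix")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each bias row must sum to 1")
    out: list[str] = []
    while len(out) < n:
        idx = np.array([rng.choice(4, p=w[j]) for j in range(BARCODE_LENGTH)])
        bases = "".join(DNA_BASES[i] for i in idx)
        if not table.is_stop(revcomp(bases[CODON_SLICE])):
            out.append(bases)
    from .barcode_model import classify_barcode

    truth = pd.DataFrame(
        {
            "barcode": out,
            "replacement_aa": [classify_barcode(b, table=table).replacement_aa for b in out],
        }
    )
    return out, truth


def strain_amplicon(template: BarcodeTemplate, barcode: str) -> str:
    """The sequenced amplicon for one strain: pads around its repair oligo."""
    return PAD_LEFT + instantiate_oligo(template, barcode) + PAD_RIGHT


def _quality_profile(cfg: SimConfig) -> np.ndarray:
    """Per-cycle Phred scores: lower-quality tails, high-quality middle."""
    if cfg.per_base_error_rate is not None:
        if cfg.per_base_error_rate == 0:
            q = 41
        else:
            q = min(41, int(round(-10.0 * np.log10(cfg.per_base_error_rate))))
        return np.full(cfg.read_length, q, dtype=np.int64)
    q = np.full(cfg.read_length, cfg.q_mid, dtype=np.int64)
    q[: cfg.tail_len] = cfg.q_tail
    q[cfg.read_length - cfg.tail_len :] = cfg.q_tail
    return q


def _sequence_reads(
    amplicon: str, n: int, cfg: SimConfig, rng: np.random.Generator, id_prefix: str
) -> list[ReadPair]:
    """Vectorised read-pair simulation for one amplicon."""
    amp = np.frombuffer(check_dna(amplicon).encode(), dtype=np.uint8)
    L, sp = cfg.read_length, cfg.spacer_len
    body = L - sp
    if body > amp.size:
        raise ValueError("read length (minus spacer) exceeds amplicon length")
    if 2 * body - amp.size < 10:
        raise ValueError("amplicon too long for mates to overlap by >= 10 nt")
    quals = _quality_profile(cfg)
    perr = 10.0 ** (-quals / 10.0)
    if cfg.per_base_error_rate is not None:
        perr = np.full(L, cfg.per_base_error_rate)
    qual_str = (quals.astype(np.uint8) + PHRED_OFFSET).tobytes().decode()
    base_index = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASE_ARR):
        base_index[b] = i

    def simulate_mate(templ: np.ndarray) -> np.ndarray:
        mat = np.tile(templ, (n, 1))
        spacers = (
            _BASE_ARR[rng.integers(0, 4, size=(n, sp))]
            if sp
            else np.empty((n, 0), np.uint8)
        )
        reads = np.concatenate([spacers, mat], axis=1)
        err = rng.random((n, L)) < perr[None, :]
        shift = rng.integers(1, 4, size=int(err.sum()))
        reads[err] = _BASE_ARR[(base_index[reads[err]] + shift) % 4]
        return reads

    r1 = simulate_mate(amp[:body])
    r2 = simulate_mate(np.frombuffer(revcomp(amplicon).encode(), dtype=np.uint8)[:body])
    return [
        ReadPair(
            id=f"{id_prefix}:{i}",
            seq1=r1[i].tobytes().decode(),
            qual1=qual_str,
            seq2=r2[i].tobytes().decode(),
            qual2=qual_str,
        )
        for i in range(n)
    ]


def gen_read_pairs(
    cfg: SimConfig,
    whitelist: Mapping[str, str],
    proportions: Mapping[str, float],
    template: BarcodeTemplate,
    seed: int | None = None,
    sample_id: str = "sample",
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate one sample's paired FASTQ records with exact truth counts.

    ``whitelist`` maps barcode -> strain; ``proportions`` strain -> true
    proportion. Reads are drawn multinomially at the true proportions,
    mates tile the amplicon with >= 10 nt overlap, and substitution errors
    are injected at the quality-implied rate.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    strains = sorted(proportions)
    p = np.array([proportions[s] for s in strains], dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must be nonnegative and sum to 1")
    by_strain = {s: bc for bc, s in whitelist.items()}
    missing = [s for s in strains if s not in by_strain]
    if missing:
        raise ValueError(f"strains missing from whitelist: {missing}")
    counts = rng.multinomial(cfg.read_depth, p)
    pairs: list[ReadPair] = []
    for s, n in zip(strains, counts):
        if n == 0:
            continue
        amp = strain_amplicon(template, by_strain[s])
        pairs.extend(_sequence_reads(amp, int(n), cfg, rng, f"{sample_id}:{s}"))
    truth = pd.DataFrame({"strain": strains, "true_reads": counts})
    truth["true_proportion"] = p
    return pairs, truth


def _jitter(p: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Logistic-normal proportion noise: multiply by lognormal, renormalise."""
    if cv <= 0:
        return p
    f = rng.lognormal(mean=0.0, sigma=cv, size=p.size)
    q = p * f
    return q / q.sum()


def shifted_proportions(p: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Apply per-strain percentage-point shifts, then renormalise."""
    q = p + effects / 100.0
    if np.any(q < 0):
        raise ValueError("effects drive a proportion below zero")
    return q / q.sum()


@dataclass(frozen=True)
class CompetitionSample:
    experiment: int
    technical: int | None  # None for the shared T0 mixture sample
    condition: str  # "t0", "washed", "unwashed"
    sample_id: str
    pairs: list[ReadPair]
    truth: pd.DataFrame


@dataclass(frozen=True)
class CompetitionSim:
    strains: tuple[str, ...]
    samples: tuple[CompetitionSample, ...]
    truth_delta: pd.DataFrame  # per experiment x strain true delta%, washed


def gen_competition_experiment(
    cfg: SimConfig,
    whitelist: Mapping[str, str],
    template: BarcodeTemplate,
) -> CompetitionSim:
    """Simulate a washed/unwashed competition with replicate structure.

    Per experiment: one shared T0 mixture sample plus ``n_technical``
    washed and unwashed TF wells. Unwashed TF proportions equal the
    experiment's T0 proportions; washed TF proportions are shifted by the
    configured effects and renormalised. Biological noise perturbs each
    experiment's mixture; technical noise perturbs each sequenced sample.
    """
    strains = tuple(sorted(set(whitelist.values())))
    if len(strains) != cfg.n_strains:
        raise ValueError(
            f"whitelist covers {len(strains)} strains, config says {cfg.n_strains}"
        )
    unknown = set(cfg.effects) - set(strains)
    if unknown:
        raise ValueError(f"effects name unknown strains: {sorted(unknown)}")
    effects = np.array([cfg.effects.get(s, 0.0) for s in strains])
    p0 = cfg.proportions()
    rng = np.random.default_rng(cfg.seed)
    samples: list[CompetitionSample] = []
    truth_rows = []
    for e in range(1, cfg.n_experiments + 1):
        base = _jitter(p0, cfg.biological_cv, rng)
        washed_true = shifted_proportions(base, effects)
        for s, d in zip(strains, 100.0 * (washed_true - base)):
            truth_rows.append({"experiment": e, "strain": s, "true_delta_percent": d})
        plan = [("t0", None, base)]
        plan += [("washed", r, washed_true) for r in range(1, cfg.n_technical + 1)]
        plan += [("unwashed", r, base) for r in range(1, cfg.n_technical + 1)]
        for condition, tech, true_p in plan:
            noisy = _jitter(true_p, cfg.technical_cv, rng)
            sid = f"exp{e}_{condition}" + (f"_rep{tech}" if tech else "")
            pairs, truth = gen_read_pairs(
                cfg,
                whitelist,
                dict(zip(strains, noisy)),
                template,
                seed=int(rng.integers(0, 2**31)),
                sample_id=sid,
            )
            samples.append(
                CompetitionSample(
                    experiment=e,
                    technical=tech,
                    condition=condition,
                    sample_id=sid,
                    pairs=pairs,
                    truth=truth,
                )
            )
    return CompetitionSim(
        strains=strains,
        samples=tuple(samples),
        truth_delta=pd.DataFrame(truth_rows),
    )


def gen_cfu_series(
    cfg: SimConfig, group: str = "wt", slope: float | None = None
) -> tuple[list[CFUSeries], pd.DataFrame]:
    """Fecal CFU time courses: log10-linear decay, Gaussian noise, LOD censoring.

    Values falling below the detection limit are recorded *at* the limit
    with a censoring flag in the truth table (plates show no colonies; the
    series object carries the limit for the fit's LOD policy).
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.clearance_slope if slope is None else slope
    series: list[CFUSeries] = []
    rows = []
    for subj in range(1, cfg.n_subjects + 1):
        log10 = (
            cfg.log10_cfu0
            - s * np.asarray(cfg.days)
            + rng.normal(0.0, cfg.clearance_noise_sd, len(cfg.days))
        )
        cfu = 10.0**log10
        censored = cfu < cfg.lod
        observed = np.where(censored, cfg.lod, cfu)
        sid = f"{group}{subj}"
        series.append(
            CFUSeries(
                subject_id=sid,
                days=tuple(cfg.days),
                cfu_per_100mg=tuple(observed),
                detection_limit=cfg.lod,
            )
        )
        for d, c, cen in zip(cfg.days, observed, censored):
            rows.append(
                {
                    "subject": sid,
                    "day": d,
                    "cfu_per_100mg": c,
                    "censored": bool(cen),
                    "true_slope": -s,
                }
            )
    return series, pd.DataFrame(rows)


def gen_growth_curves(
    cfg: SimConfig,
    n_curves: int = 3,
    t_max_h: float = 12.0,
    dt_h: float = 0.5,
) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Logistic OD600 curves with a lag phase and multiplicative noise.

    The configured ``growth_rate`` (doublings/h) is the maximal exponential
    rate; the truth table records it for oracle comparisons.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, t_max_h + dt_h / 2, dt_h)
    r = cfg.growth_rate * np.log(2.0)  # per-hour exponential rate
    curves: list[GrowthCurve] = []
    rows = []
    for i in range(n_curves):
        te = np.clip(t - cfg.growth_lag_h, 0.0, None)
        od = cfg.od_capacity / (
            1.0 + (cfg.od_capacity / cfg.od0 - 1.0) * np.exp(-r * te)
        )
        if cfg.growth_noise_cv > 0:
            od = od * rng.lognormal(0.0, cfg.growth_noise_cv, t.size)
        curves.append(GrowthCurve(time_h=tuple(t), od600=tuple(od)))
        rows.append({"curve": i, "true_rate_doublings_per_h": cfg.growth_rate})
    return curves, pd.DataFrame(rows)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """A copy of ``cfg`` with a different seed (convenience for sweeps)."""
    return replace(cfg, seed=seed)
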