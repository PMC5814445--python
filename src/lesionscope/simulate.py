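"""Fully synthetic multi-platform cohort generator.

Emulates the statistical structure of a mature T-cell leukemia cohort at
desk scale so every downstream stage is testable without any download:
somatic calls with clonal/subclonal VAF structure and an oxidative
C:G>A:T excess with read-orientation bias, copy-number segments spanning
loss/neutral/gain/UPD states (optionally with a planted common deletion),
survival-associated expression probes with exponential survival times,
and Hill-shaped 7x7 dose-response plates with a configurable interaction
shift.

Every record written is traceable to one entry of the truth sidecar, and
all randomness flows from one seed through per-output labeled substreams
(adding one output never shifts another).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .cna import GeneTable, Segment
from .filtering import VariantCall
from .synergy import DoseResponsePlate

__all__ = [
    "CohortConfig",
    "HillParams",
    "CohortBundle",
    "simulate_variant_reads",
    "simulate_plate",
    "simulate_cohort",
    "DEFAULT_DRUGS",
    "DEFAULT_COMBINATIONS",
]

_NAMED_GENES = (
    "TCL1A", "ATM", "AGO2", "AGO1", "AGO3", "AGO4", "MYC",
    "IL2RG", "JAK1", "JAK3", "STAT5B", "TP53", "POT1", "EZH2", "KAT6B",
)

GENE_LEN = 150
GENE_GAP = 50
N_CONTIGS = 4
_MDR_EXT_MAX = 3   # max per-case gene extension around a planted deletion


@dataclass(frozen=True)
class HillParams:
    """Monotherapy dose-response on the inhibition-fraction scale [0, 1]."""

    emin: float = 0.0
    emax: float = 0.6
    ec50: float = 50.0     # nM
    slope: float = 1.0

    def response(self, dose: np.ndarray | float) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return self.emin + (self.emax - self.emin) / (
            1.0 + (self.ec50 / dose) ** self.slope)


DEFAULT_DRUGS: dict[str, HillParams] = {
    "I": HillParams(ec50=20.0),
    "P": HillParams(ec50=50.0),
    "B": HillParams(ec50=80.0),
    "O": HillParams(ec50=120.0),
}
DEFAULT_COMBINATIONS = (
    ("I", "P"), ("I", "B"), ("I", "O"), ("P", "B"), ("O", "B"), ("O", "P"))
# true low-dose interaction (percentage points) per combination
DEFAULT_INTERACTIONS = {
    ("I", "P"): 8.0, ("I", "B"): 7.0, ("I", "O"): 6.0,
    ("P", "B"): 5.0, ("O", "B"): -4.0, ("O", "P"): -5.0,
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Cohort sizes default to the study's platform scales (83 array cases
    of which the first 54 carry exome calls and the first 70 expression
    profiles).  Probabilities are validated to sum to 1; the same seed
    always yields byte-identical output files.
    """

    n_cases: int = 83
    n_wes_cases: int = 54
    n_gep_cases: int = 70
    n_genes: int = 1000
    n_probes: int = 500
    clonal_vaf_mean: float = 0.35
    subclonal_vaf_mean: float = 0.12
    clonal_fraction: float = 0.6
    burden_mean: float = 70.0          # somatic calls per WES case
    depth_mean: float = 80.0
    oxo_artifact_rate: float = 0.15    # injected orientation-bias artifacts
    germline_leak_rate: float = 0.08   # calls with population MAF >= 0.01
    cga_class_fraction: float = 0.35   # oxidative C:G>A:T excess
    cn_state_probs: dict[str, float] = field(default_factory=lambda: {
        "loss": 0.35, "neutral": 0.30, "gain": 0.20, "UPD": 0.15})
    alteration_runs_mean: float = 4.0  # candidate CN runs per case
    planted_mdr: tuple[int, int] | None = None   # gene-index span on chr1
    planted_mdr_freq: float = 0.3
    survival_assoc_probes: int = 3
    survival_effect: float = 1.2       # log-hazard per SD of latent risk
    probe_loading: float = 1.5         # log2 units per SD of latent risk
    baseline_hazard: float = 1.0 / 700.0   # per day
    n_plate_cases: int = 13
    plate_noise_sd: float = 100.0      # luminescence units
    plate_neg_level: float = 10000.0
    plate_pos_level: float = 500.0
    purity_range: tuple[float, float] = (0.9, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_genes", "n_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_wes_cases", "n_gep_cases", "n_plate_cases"):
            if not 0 <= getattr(self, name) <= self.n_cases:
                raise ValueError(f"{name} must lie in [0, n_cases]")
        for name in ("clonal_vaf_mean", "subclonal_vaf_mean",
                     "oxo_artifact_rate", "germline_leak_rate",
                     "clonal_fraction", "cga_class_fraction",
                     "planted_mdr_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        probs = self.cn_state_probs
        if set(probs) != {"loss", "neutral", "gain", "UPD"}:
            raise ValueError(
                "cn_state_probs must cover loss/neutral/gain/UPD")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("cn_state_probs must sum to 1")
        if self.planted_mdr is not None:
            i0, i1 = self.planted_mdr
            per = self.n_genes // N_CONTIGS
            if not 0 <= i0 <= i1 < per:
                raise ValueError("planted_mdr span outside chr1 gene range")
        lo, hi = self.purity_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")
        if self.plate_noise_sd < 0:
            raise ValueError("plate_noise_sd must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    def rng(self, label: str) -> np.random.Generator:
        """Labeled substream: stable under addition of other outputs."""
        h = int.from_bytes(
            hashlib.sha256(label.encode()).digest()[:4], "big") % (2 ** 31)
        return np.random.default_rng([self.seed, h])


def simulate_variant_reads(
    true_vaf: float,
    depth: int,
    artifact: bool,
    rng: np.random.Generator | int,
    orientation_concentration: float = 0.98,
) -> tuple[int, int, int]:
    """Binomial read counts with optional orientation bias.

    Returns (alt_f1r2, alt_f2r1, ref_count).  Genuine calls split the
    alternate reads ~50/50 between orientations; artifact calls
    concentrate them on the F2R1 orientation (the C>A artifact
    convention; swap the two counts for the G>T strand).
    """
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError(f"true_vaf must lie in [0, 1], got {true_vaf}")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    alt_total = int(rng.binomial(depth, true_vaf))
    p = orientation_concentration if artifact else 0.5
    alt_f2r1 = int(rng.binomial(alt_total, p)) if alt_total else 0
    return alt_total - alt_f2r1, alt_f2r1, depth - alt_total


def default_doses(n: int = 7, span: float = 1000.0) -> np.ndarray:
    """Log-spaced concentrations covering a ``span``-fold range, in nM."""
    return np.logspace(0.0, np.log10(span), n)


def simulate_plate(
    hill_a: HillParams,
    hill_b: HillParams,
    interaction: float,
    noise_sd: float,
    rng: np.random.Generator | int,
    doses: np.ndarray | None = None,
    drug_a: str = "A",
    drug_b: str = "B",
    plate_id: str = "plate",
    neg_level: float = 10000.0,
    pos_level: float = 500.0,
    n_controls: int = 4,
) -> DoseResponsePlate:
    """One combination plate on the raw-luminescence scale.

    Combination wells follow the zero-interaction surface of the two
    Hill curves shifted by ``interaction`` percentage points, plus
    Gaussian noise; monotherapy wells follow the pure curves; controls
    sit at the configured plateaus.  Span-normalizing a noiseless plate
    therefore returns exactly the constructed surface.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if doses is None:
        doses = default_doses()
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("concentrations must be positive")
    ya = hill_a.response(doses)
    yb = hill_b.response(doses)
    y_zip = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    y_obs = y_zip + interaction / 100.0

    def raw(y):
        return neg_level - np.asarray(y) * (neg_level - pos_level)

    noise = lambda shape: (rng.normal(0.0, noise_sd, shape)  # noqa: E731
                           if noise_sd > 0 else np.zeros(shape))
    grid = pd.DataFrame(raw(y_obs) + noise(y_obs.shape),
                        index=doses, columns=doses)
    mono_a = pd.Series(raw(ya) + noise(ya.shape), index=doses)
    mono_b = pd.Series(raw(yb) + noise(yb.shape), index=doses)
    pos = list(pos_level + noise(n_controls))
    neg = list(neg_level + noise(n_controls))
    return DoseResponsePlate(
        drug_a=drug_a, drug_b=drug_b, grid=grid,
        mono_a=mono_a, mono_b=mono_b, pos=pos, neg=neg, plate_id=plate_id)


# ---------------------------------------------------------------------------
# whole-cohort generation


@dataclass
class CohortBundle:
    config: CohortConfig
    outdir: Path
    paths: dict[str, Path]
    truth: dict
    gene_table: GeneTable
    calls: list[VariantCall]
    call_samples: list[str]
    segments: list[Segment]
    loh_flags: pd.DataFrame
    expression: pd.DataFrame
    survival: pd.DataFrame
    plates: list[DoseResponsePlate]
    plate_cases: dict[str, list[DoseResponsePlate]]


def _make_genome(cfg: CohortConfig, rng: np.random.Generator):
    per = cfg.n_genes // N_CONTIGS
    counts = [per] * N_CONTIGS
    counts[-1] += cfg.n_genes - per * N_CONTIGS
    contigs, rows = {}, []
    g = 0
    for ci, n_on in enumerate(counts):
        chrom = f"chr{ci + 1}"
        length = n_on * (GENE_LEN + GENE_GAP) + GENE_GAP
        contigs[chrom] = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, length)])
        for k in range(n_on):
            start = GENE_GAP + k * (GENE_LEN + GENE_GAP) + 1
            name = (_NAMED_GENES[g] if g < len(_NAMED_GENES)
                    else f"G{g + 1:04d}")
            rows.append({"gene": name, "chrom": chrom, "start": start,
                         "end": start + GENE_LEN - 1})
            g += 1
    table = pd.DataFrame(rows)
    return contigs, GeneTable(table)


def _simulate_cn(cfg: CohortConfig, genes: GeneTable, cases: list[str]):
    """Per-gene CN states, LOH flags, and the tiling segment list."""
    rng = cfg.rng("cn")
    gframe = genes.frame
    n_genes = len(gframe)
    cn = np.full((n_genes, len(cases)), 2.0)
    loh = np.zeros((n_genes, len(cases)), dtype=bool)
    state = np.full((n_genes, len(cases)), "neutral", dtype=object)
    states = ["loss", "neutral", "gain", "UPD"]
    probs = [cfg.cn_state_probs[s] for s in states]
    chr1_idx = np.flatnonzero(gframe["chrom"].to_numpy() == "chr1")

    def apply_run(ci: int, idx: np.ndarray, st: str, r: np.random.Generator):
        if st == "neutral":
            return
        if st == "loss":
            val = r.uniform(0.7, 1.4)
            cn[idx, ci] = val
            loh[idx, ci] = True
        elif st == "gain":
            cn[idx, ci] = r.uniform(2.6, 3.8)
        elif st == "UPD":
            cn[idx, ci] = r.uniform(1.95, 2.05)
            loh[idx, ci] = True
        state[idx, ci] = st

    # planted common deletion on chr1 (exact span for the first affected
    # case so the minimal region is recoverable exactly)
    planted_cases: list[str] = []
    if cfg.planted_mdr is not None:
        i0, i1 = cfg.planted_mdr
        n_aff = max(1, int(round(cfg.planted_mdr_freq * len(cases))))
        chosen = rng.choice(len(cases), size=n_aff, replace=False)
        for j, ci in enumerate(sorted(chosen)):
            ext_l = 0 if j == 0 else int(rng.integers(0, _MDR_EXT_MAX + 1))
            ext_r = 0 if j == 0 else int(rng.integers(0, _MDR_EXT_MAX + 1))
            lo = max(0, i0 - ext_l)
            hi = min(len(chr1_idx) - 1, i1 + ext_r)
            apply_run(ci, chr1_idx[lo:hi + 1], "loss", rng)
            planted_cases.append(cases[ci])

    by_chrom = {c: np.flatnonzero(gframe["chrom"].to_numpy() == c)
                for c in gframe["chrom"].unique()}
    for ci in range(len(cases)):
        n_runs = rng.poisson(cfg.alteration_runs_mean)
        for _ in range(n_runs):
            st = states[rng.choice(4, p=probs)]
            chrom = gframe["chrom"].unique()[rng.integers(0, N_CONTIGS)]
            idx = by_chrom[chrom]
            start = int(rng.integers(0, len(idx)))
            length = int(rng.integers(1, 30))
            run = idx[start:start + length]
            # keep random runs off the planted span and its extension
            # margin, so the planted frequency strictly dominates its
            # flanking genes and the minimal region stays recoverable
            if cfg.planted_mdr is not None and chrom == "chr1":
                i0, i1 = cfg.planted_mdr
                lo = chr1_idx[0] + i0 - _MDR_EXT_MAX
                hi = chr1_idx[0] + i1 + _MDR_EXT_MAX
                run = run[(run < lo) | (run > hi)]
            if run.size:
                apply_run(ci, run, st, rng)

    # tile each contig into segments over runs of equal per-gene CN
    starts = gframe["start"].to_numpy()
    ends = gframe["end"].to_numpy()
    segments: list[Segment] = []
    for ci, case in enumerate(cases):
        for chrom, idx in by_chrom.items():
            bounds_lo = np.empty(len(idx), dtype=int)
            bounds_hi = np.empty(len(idx), dtype=int)
            bounds_lo[0] = 1
            for k in range(1, len(idx)):
                mid = (ends[idx[k - 1]] + starts[idx[k]]) // 2
                bounds_hi[k - 1] = mid
                bounds_lo[k] = mid + 1
            bounds_hi[-1] = ends[idx[-1]] + GENE_GAP
            k = 0
            while k < len(idx):
                j = k
                while (j + 1 < len(idx)
                       and cn[idx[j + 1], ci] == cn[idx[k], ci]):
                    j += 1
                segments.append(Segment(
                    sample=case, chrom=chrom,
                    start=int(bounds_lo[k]), end=int(bounds_hi[j]),
                    cn=float(cn[idx[k], ci]),
                    n_markers=int(j - k + 1)))
                k = j + 1
    loh_df = pd.DataFrame(loh, index=gframe["gene"], columns=cases)
    cn_df = pd.DataFrame(cn, index=gframe["gene"], columns=cases)
    state_df = pd.DataFrame(state, index=gframe["gene"], columns=cases)
    return cn_df, loh_df, state_df, segments, planted_cases


_SUB_WEIGHTS = {   # non-oxidative substitution profile (transition-heavy)
    "A": ("GCT", (0.6, 0.2, 0.2)),
    "C": ("TGA", (0.6, 0.2, 0.2)),
    "G": ("ACT", (0.6, 0.2, 0.2)),
    "T": ("CAG", (0.6, 0.2, 0.2)),
}


def _simulate_variants(cfg: CohortConfig, contigs, genes: GeneTable,
                       wes_cases: list[str], purity: dict[str, float]):
    rng = cfg.rng("variants")
    gframe = genes.frame
    weights = np.ones(len(gframe))
    name_arr = gframe["gene"].to_numpy()
    for gene, w in (("ATM", 20.0), ("JAK3", 8.0), ("JAK1", 6.0),
                    ("STAT5B", 6.0), ("IL2RG", 4.0), ("TP53", 4.0)):
        weights[name_arr == gene] = w
    weights /= weights.sum()
    calls: list[VariantCall] = []
    samples: list[str] = []
    truth_rows: list[dict] = []
    seen_pos: set[tuple[str, str, int]] = set()
    for case in wes_cases:
        n_var = int(rng.poisson(cfg.burden_mean))
        for _ in range(n_var):
            artifact = rng.random() < cfg.oxo_artifact_rate
            want_cga = artifact or (rng.random() < cfg.cga_class_fraction)
            for _try in range(50):
                gi = int(rng.choice(len(gframe), p=weights))
                pos = int(rng.integers(gframe["start"].iloc[gi] + 1,
                                       gframe["end"].iloc[gi] - 1))
                chrom = gframe["chrom"].iloc[gi]
                ref = contigs[chrom][pos - 1]
                if (case, chrom, pos) in seen_pos:
                    continue
                if not want_cga or ref in "CG":
                    break
            else:
                continue
            seen_pos.add((case, chrom, pos))
            if want_cga and ref in "CG":
                alt = "A" if ref == "C" else "T"
            else:
                choices, p = _SUB_WEIGHTS[ref]
                alt = choices[rng.choice(3, p=p)]
            clonal = rng.random() < cfg.clonal_fraction
            mean = (cfg.clonal_vaf_mean if clonal
                    else cfg.subclonal_vaf_mean)
            if artifact:
                true_vaf = float(rng.uniform(0.04, 0.15))
            else:
                true_vaf = float(np.clip(rng.normal(mean, 0.03), 0.02, 0.95))
            depth = max(10, int(rng.poisson(cfg.depth_mean)))
            f1r2, f2r1, _refn = simulate_variant_reads(
                true_vaf, depth, artifact, rng)
            if ref == "G":          # swap to the G>T artifact orientation
                f1r2, f2r1 = f2r1, f1r2
            alt_total = f1r2 + f2r1
            vaf = alt_total / depth
            if alt_total == 0:
                continue
            tumor_load = (float(rng.uniform(3.0, 12.0)) if artifact
                          else float(rng.uniform(20.0, 90.0)))
            pop = {}
            if rng.random() < cfg.germline_leak_rate:
                src = ("1000G", "ESP6500", "ExAC")[rng.integers(0, 3)]
                pop[src] = float(rng.uniform(0.01, 0.4))
            damaging = rng.random() < 0.55
            polyphen2 = (float(rng.uniform(0.957, 1.0)) if damaging
                         else float(rng.uniform(0.0, 0.95)))
            sift = (float(rng.uniform(0.0, 0.05)) if damaging
                    else float(rng.uniform(0.06, 1.0)))
            confirmed = None
            if vaf < 0.5:
                confirmed = bool(rng.random() < (0.5 if artifact else 0.9))
            calls.append(VariantCall(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=str(name_arr[gi]), category="nonsynonymous",
                vaf=vaf, depth=depth,
                qual=float(rng.uniform(60.0, 900.0)),
                alt_f1r2=f1r2, alt_f2r1=f2r1, tumor_load=tumor_load,
                pop_freqs=pop, sift=sift, polyphen2=polyphen2,
                cosmic=bool(rng.random() < 0.08),
                confirmed_by_second_caller=confirmed,
                call_id=f"{case}:{chrom}:{pos}:{ref}>{alt}"))
            samples.append(case)
            truth_rows.append({
                "call_id": calls[-1].call_id, "case": case,
                "true_vaf": round(true_vaf, 6), "clonal": bool(clonal),
                "artifact": bool(artifact),
                "germline_leak": bool(pop),
                "purity": round(purity[case], 6)})
    return calls, samples, truth_rows


def _simulate_expression(cfg: CohortConfig, gep_cases: list[str],
                         risk: dict[str, float]):
    rng = cfg.rng("expression")
    n, m = cfg.n_probes, len(gep_cases)
    base = rng.lognormal(mean=6.0, sigma=0.6, size=(n, m))
    probes = [f"P{i + 1:04d}" for i in range(n - cfg.survival_assoc_probes)]
    probes += [f"P_surv{i + 1}" for i in range(cfg.survival_assoc_probes)]
    u = np.array([risk[c] for c in gep_cases])
    effects = {}
    for i in range(cfg.survival_assoc_probes):
        row = n - cfg.survival_assoc_probes + i
        sign = 1.0 if i % 2 == 0 else -1.0
        loading = sign * cfg.probe_loading
        base[row] = np.exp(
            6.0 + loading * np.log(2) * u + rng.normal(0, 0.2, m))
        effects[probes[row]] = loading
    # probe 1 tracks TCL1A with a bimodal high/low pattern
    high = rng.random(m) < 0.6
    base[0] = np.where(high,
                       rng.lognormal(8.0, 0.3, m), rng.lognormal(5.5, 0.3, m))
    expr = pd.DataFrame(np.round(base, 4), index=probes, columns=gep_cases)
    return expr, effects, pd.Series(high, index=gep_cases)


def _simulate_survival(cfg: CohortConfig, cases: list[str]):
    rng = cfg.rng("survival")
    risk = {c: float(rng.normal()) for c in cases}
    rows = []
    for c in cases:
        rate = cfg.baseline_hazard * float(np.exp(
            cfg.survival_effect * risk[c]))
        t = float(rng.exponential(1.0 / rate))
        censor = float(rng.uniform(100.0, 2500.0))
        rows.append({"case": c, "time": round(min(t, censor), 2),
                     "event": int(t <= censor)})
    surv = pd.DataFrame(rows).set_index("case")
    return surv, risk


def _simulate_plates(cfg: CohortConfig, plate_cases: list[str]):
    plates: list[DoseResponsePlate] = []
    by_case: dict[str, list[DoseResponsePlate]] = {c: [] for c in plate_cases}
    truth = []
    for case in plate_cases:
        for da, db in DEFAULT_COMBINATIONS:
            rng = cfg.rng(f"plate:{case}:{da}+{db}")
            inter = DEFAULT_INTERACTIONS[(da, db)] + float(rng.normal(0, 1.5))
            plate = simulate_plate(
                DEFAULT_DRUGS[da], DEFAULT_DRUGS[db], inter,
                cfg.plate_noise_sd, rng,
                drug_a=da, drug_b=db,
                plate_id=f"{case}:{da}+{db}",
                neg_level=cfg.plate_neg_level,
                pos_level=cfg.plate_pos_level)
            plates.append(plate)
            by_case[case].append(plate)
            truth.append({"plate_id": plate.plate_id, "case": case,
                          "drug_a": da, "drug_b": db,
                          "true_delta": round(inter, 6),
                          "hill_a": vars(DEFAULT_DRUGS[da]),
                          "hill_b": vars(DEFAULT_DRUGS[db])})
    return plates, by_case, truth


def simulate_cohort(config: CohortConfig, outdir: str | Path) -> CohortBundle:
    """Generate and write the full multi-platform bundle.

    Writes (under ``outdir``): reference.fa, genes.tsv, variants.tsv,
    variants.vcf, segments.seg, loh_flags.tsv, expression.tsv,
    survival.tsv, plates.csv, and the truth sidecar truth.json.
    Deterministic: the same config (including seed) always produces
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cases = [f"TP{i + 1:03d}" for i in range(config.n_cases)]
    wes_cases = cases[:config.n_wes_cases]
    gep_cases = cases[:config.n_gep_cases]
    plate_cases = cases[:config.n_plate_cases]

    contigs, gene_table = _make_genome(config, config.rng("genome"))
    purity_rng = config.rng("purity")
    purity = {c: float(purity_rng.uniform(*config.purity_range))
              for c in cases}
    cn_df, loh_df, state_df, segments, planted_cases = _simulate_cn(
        config, gene_table, cases)
    calls, call_samples, var_truth = _simulate_variants(
        config, contigs, gene_table, wes_cases, purity)
    surv, risk = _simulate_survival(config, cases)
    expr, probe_effects, tcl1a_high = _simulate_expression(
        config, gep_cases, risk)
    plates, plates_by_case, plate_truth = _simulate_plates(
        config, plate_cases)

    paths = {k: outdir / v for k, v in {
        "reference": "reference.fa", "genes": "genes.tsv",
        "variants_tsv": "variants.tsv", "variants_vcf": "variants.vcf",
        "segments": "segments.seg", "loh_flags": "loh_flags.tsv",
        "expression": "expression.tsv", "survival": "survival.tsv",
        "plates": "plates.csv", "truth": "truth.json"}.items()}
    with open(paths["reference"], "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    gene_table.frame.to_csv(paths["genes"], sep="\t", index=False)
    lio.write_variants_tsv(calls, paths["variants_tsv"],
                           samples=call_samples)
    lio.write_vcf(calls, paths["variants_vcf"], samples=call_samples,
                  contigs={k: len(v) for k, v in contigs.items()})
    lio.write_seg(segments, paths["segments"])
    loh_df.astype(int).to_csv(paths["loh_flags"], sep="\t")
    expr.to_csv(paths["expression"], sep="\t")
    surv.to_csv(paths["survival"], sep="\t")
    lio.write_plates_csv(plates, paths["plates"])

    altered = {
        case: {g: {"state": state_df.loc[g, case],
                   "cn": round(float(cn_df.loc[g, case]), 6)}
               for g in state_df.index[state_df[case] != "neutral"]}
        for case in cases}
    truth = {
        "config": {f.name: getattr(config, f.name)
                   for f in fields(config)
                   if f.name not in ("cn_state_probs",)},
        "cn_state_probs": config.cn_state_probs,
        "purity": {c: round(purity[c], 6) for c in cases},
        "risk": {c: round(risk[c], 6) for c in cases},
        "variants": var_truth,
        "cn_altered_genes": altered,
        "planted_mdr": (
            None if config.planted_mdr is None
            else {"span": list(config.planted_mdr),
                  "cases": planted_cases}),
        "probe_effects": probe_effects,
        "tcl1a_high": {c: bool(v) for c, v in tcl1a_high.items()},
        "plates": plate_truth,
    }
    lio.write_json(truth, paths["truth"])
    return CohortBundle(
        config=config, outdir=outdir, paths=paths, truth=truth,
        gene_table=gene_table, calls=calls, call_samples=call_samples,
        segments=segments, loh_flags=loh_df, expression=expr,
        survival=surv, plates=plates, plate_cases=plates_by_case)
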