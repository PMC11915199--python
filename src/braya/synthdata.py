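"""Synthetic data generators with known ground truth for every pipeline stage.

Each generator is a deterministic function of its config (which carries the
seed) and mirrors the statistical structure the corresponding analysis
assumes: clonal genotype clusters with controlled pairwise identity-by-state
dissimilarity, closed-respirometry oxygen traces with known consumption,
diffusion and background rates and a known critical oxygen limit, and
time-to-immobilization records with run and clone random effects plus a
subpopulation fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .respirometry import OxygenTrace

__all__ = [
    "GenotypeSimConfig",
    "TraceSimConfig",
    "TimmSimConfig",
    "SimulatedGenotypes",
    "SimulatedRespirometry",
    "simulate_genotypes",
    "simulate_traces",
    "simulate_pcrit_profile",
    "simulate_timm",
]


# -- genotypes ----------------------------------------------------------------

# Per-locus dosage perturbation replaces the current dosage by a uniform draw
# from the other ploidy levels.  For two genotypes independently perturbed
# from a common base at rates r1, r2, the expected per-locus dissimilarity
# |d1 - d2| / ploidy is (for ploidy 3):
#   E = (r1 + r2 - 2 r1 r2) * 5/9 + r1 r2 * 10/27
# (5/9: one side perturbed; 10/27: both perturbed).  This is inverted to
# calibrate the rates to a target mean pairwise 1 - IBS.
_ONE_SIDED = 5.0 / 9.0
_BOTH_SIDED = 10.0 / 27.0


def _expected_dissim(r1: float, r2: float) -> float:
    return (r1 + r2 - 2 * r1 * r2) * _ONE_SIDED + r1 * r2 * _BOTH_SIDED


def _solve_symmetric_rate(target: float) -> float:
    """Per-side perturbation rate r with E(r, r) = target (ploidy 3)."""
    # E(r, r) = 2r(1-r)*5/9 + r^2*10/27 = (10/9) r - (20/27) r^2
    a, b, c = -20.0 / 27.0, 10.0 / 9.0, -target
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError(
            f"divergence target {target} unreachable; the maximum expected "
            f"pairwise dissimilarity under this perturbation model is "
            f"{_expected_dissim(1.0, 1.0):.4f}"
        )
    r = (-b + np.sqrt(disc)) / (2 * a)  # smaller root
    if not 0 <= r <= 1:
        raise ValueError(f"no valid perturbation rate for target {target}")
    return float(r)


@dataclass
class GenotypeSimConfig:
    """Clonal genotype clusters with controlled IBS dissimilarity.

    ``between_dissimilarity`` maps cluster index pairs to target mean pairwise
    1 - IBS between their clones; the defaults sit inside the 8.75%-11.49%
    (historical-mixed) and 8.91%-13.33% (either-to-modern) bands observed for
    the study system.  ``within_dissimilarity`` is the target 1 - IBS between
    clones of the same cluster.
    """

    n_clusters: int = 3
    clones_per_cluster: tuple[int, ...] = (5, 9, 9)
    n_snps: int = 5000
    ploidy: int = 3
    within_dissimilarity: float = 0.01
    between_dissimilarity: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: {(0, 1): 0.10, (0, 2): 0.11, (1, 2): 0.11}
    )
    missing_rate: float = 0.02
    depth_mean: float = 30.0
    depth_overdispersion: float = 5.0
    multiallelic_rate: float = 0.0
    site_fail_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.clones_per_cluster) != self.n_clusters:
            raise ValueError("clones_per_cluster length must equal n_clusters")
        targets = list(self.between_dissimilarity.values())
        if any(not 0 <= t <= 1 for t in targets + [self.within_dissimilarity]):
            raise ValueError("divergence fractions must lie in [0, 1]")
        if targets and self.within_dissimilarity >= min(targets):
            raise ValueError("within-cluster divergence must be below every between-cluster target")


@dataclass
class SimulatedGenotypes:
    table: "GenotypeTable"
    labels: pd.Series  # sample_id -> cluster index
    cluster_names: list[str]
    realized_between: dict[tuple[int, int], float]
    realized_within: float
    vcf_text: str

    def to_vcf(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.write(self.vcf_text)
        return path


def _calibrate_cluster_rates(config: GenotypeSimConfig) -> tuple[np.ndarray, float]:
    """Per-cluster base-perturbation rates hitting the pairwise targets."""
    from scipy.optimize import least_squares

    w = _solve_symmetric_rate(config.within_dissimilarity) if config.within_dissimilarity > 0 else 0.0
    k = config.n_clusters
    pairs = sorted(config.between_dissimilarity)
    if not pairs:
        return np.zeros(k), w
    targets = np.array([config.between_dissimilarity[p] for p in pairs])
    if np.any(targets >= _expected_dissim(1.0, 1.0)):
        raise ValueError(
            f"between-cluster target exceeds the achievable bound "
            f"{_expected_dissim(1.0, 1.0):.4f} of the perturbation model"
        )

    def resid(a):
        return np.array(
            [_expected_dissim(a[i] + w, a[j] + w) - t for (i, j), t in zip(pairs, targets)]
        )

    x0 = np.full(k, 0.9 * float(targets.mean()) / 2 if len(targets) else 0.05)
    sol = least_squares(resid, x0, bounds=(0.0, 0.95))
    if np.max(np.abs(sol.fun)) > 0.005:
        raise ValueError(
            "between-cluster divergence targets are jointly unreachable; "
            f"best residual {np.max(np.abs(sol.fun)):.4f}"
        )
    return sol.x, w


def _perturb(dosage: np.ndarray, rate: float, rng: np.random.Generator, ploidy: int) -> np.ndarray:
    out = dosage.copy()
    hit = rng.random(len(out)) < rate
    if hit.any():
        shift = rng.integers(1, ploidy + 1, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % (ploidy + 1)
    return out


_BASES = np.array(list("ACGT"))


def _vcf_text(config: GenotypeSimConfig, sample_ids, dosage, depth, rng) -> str:
    n_samples, n_snps = dosage.shape
    positions = np.sort(rng.choice(np.arange(1, n_snps * 20), size=n_snps, replace=False))
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_shift = rng.integers(1, 4, size=n_snps)
    multi = rng.random(n_snps) < config.multiallelic_rate
    fail = rng.random(n_snps) < config.site_fail_rate
    fail_modes = rng.integers(0, 4, size=n_snps)

    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=1,length={int(positions[-1]) + 1000}>",
        '##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate allele observation count">',
        '##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alt observations on the forward strand">',
        '##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alt observations on the reverse strand">',
        '##INFO=<ID=RPR,Number=1,Type=Integer,Description="Reads placed right of the alt allele">',
        '##INFO=<ID=RPL,Number=1,Type=Integer,Description="Reads placed left of the alt allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for j in range(n_snps):
        ref = _BASES[ref_idx[j]]
        alt = _BASES[(ref_idx[j] + alt_shift[j]) % 4]
        alt_field = alt if not multi[j] else alt + "," + _BASES[(ref_idx[j] + alt_shift[j] + 1) % 4]
        col_dos = dosage[:, j]
        col_dep = depth[:, j]
        ao = 0.0
        for i in range(n_samples):
            if not np.isnan(col_dos[i]) and not np.isnan(col_dep[i]):
                ao += col_dos[i] / config.ploidy * col_dep[i]
        ao = max(int(round(ao)), 2)
        saf = ao // 2
        sar = ao - saf
        rpr = rpl = max(2, ao // 2)
        qual = round(12.5 * ao + 1.0, 1)
        if fail[j]:
            mode = fail_modes[j]
            if mode == 0:
                qual = 0.5  # fails QUAL > 1
            elif mode == 1:
                qual = round(5.0 * ao, 1)  # fails QUAL/AO > 10
            elif mode == 2:
                saf, sar = 0, ao  # strand bias
            else:
                rpr, rpl = 1, 1  # placement bias
        info = f"AO={ao};SAF={saf};SAR={sar};RPR={rpr};RPL={rpl}"
        gts = []
        for i in range(n_samples):
            if np.isnan(col_dos[i]):
                gt = "/".join(["."] * config.ploidy)
            else:
                d = int(col_dos[i])
                gt = "/".join(["0"] * (config.ploidy - d) + ["1"] * d)
            dp = "." if np.isnan(col_dep[i]) else str(int(col_dep[i]))
            gts.append(f"{gt}:{dp}")
        lines.append(
            f"1\t{int(positions[j])}\t.\t{ref}\t{alt_field}\t{qual}\tPASS\t{info}\tGT:DP\t"
            + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


def simulate_genotypes(config: GenotypeSimConfig | None = None) -> SimulatedGenotypes:
    """Generate clonal genotype clusters, their truth labels and a VCF.

    Cluster centroids are dosage perturbations of one base genotype at rates
    calibrated so that the expected mean pairwise 1 - IBS between clusters
    matches the configured targets; clones perturb their centroid at the
    within-cluster rate.  The realized between/within dissimilarities are
    computed post hoc and attached.
    """
    from .genotypes import GenotypeTable, ibs_matrix

    config = config or GenotypeSimConfig()
    rng = np.random.default_rng(config.seed)
    rates, w = _calibrate_cluster_rates(config)

    base = rng.integers(0, config.ploidy + 1, size=config.n_snps).astype(float)
    centroids = [_perturb(base, rates[k], rng, config.ploidy) for k in range(config.n_clusters)]

    sample_ids, labels, rows = [], [], []
    for k, n_clones in enumerate(config.clones_per_cluster):
        for c in range(n_clones):
            sample_ids.append(f"C{k}_{c:02d}")
            labels.append(k)
            rows.append(_perturb(centroids[k], w, rng, config.ploidy))
    dosage = np.array(rows)

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    m, disp = config.depth_mean, config.depth_overdispersion
    depth = rng.negative_binomial(disp, disp / (disp + m), size=dosage.shape).astype(float)
    depth[np.isnan(dosage)] = np.nan

    vcf_text = _vcf_text(config, sample_ids, dosage, depth, rng)

    table = GenotypeTable(
        sample_ids=sample_ids,
        locus_ids=[f"1:{j}" for j in range(config.n_snps)],
        dosage=dosage,
        depth=depth,
        ploidy=config.ploidy,
    )
    lab = pd.Series(labels, index=sample_ids, name="cluster")
    diss = ibs_matrix(table).dissimilarity
    realized_between: dict[tuple[int, int], float] = {}
    for (i, j) in config.between_dissimilarity:
        mask_i = lab.to_numpy() == i
        mask_j = lab.to_numpy() == j
        realized_between[(i, j)] = float(diss[np.ix_(mask_i, mask_j)].mean())
    within_vals = []
    arr = lab.to_numpy()
    for k in range(config.n_clusters):
        idx = np.flatnonzero(arr == k)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                within_vals.append(diss[idx[a], idx[b]])
    realized_within = float(np.mean(within_vals)) if within_vals else 0.0
    return SimulatedGenotypes(
        table=table,
        labels=lab,
        cluster_names=[f"cluster{k}" for k in range(config.n_clusters)],
        realized_between=realized_between,
        realized_within=realized_within,
        vcf_text=vcf_text,
    )


# -- respirometry traces ------------------------------------------------------


@dataclass
class TraceSimConfig:
    """Closed-respirometry design: two batches of runs with a shared reference.

    Each run holds one experimental well per clone in its batch, four
    reference-clone wells and four blanks; one separate sealed run without
    animals (24 wells) measures film diffusion.  Experimental O2 declines
    linearly at (clone rate + diffusion + background) while above the critical
    oxygen limit, below which consumption scales with O2 (exponential decay).
    """

    clones_per_batch: tuple[int, ...] = (11, 12)
    runs_per_batch: int = 6
    reference_clone: str = "SS4-5"
    n_reference_wells: int = 4
    n_blank_wells: int = 4
    n_diffusion_wells: int = 24
    o2_start: float = 100.0
    duration_h: float = 6.0
    dt_min: float = 2.0
    rate_mean: float = 8.0  # % air sat / h consumed by one animal
    rate_sd: float = 3.0  # between-clone spread
    true_pcrit: float = 25.0
    diffusion_rate: float = 0.4
    background_rate: float = 0.2
    run_effect_sd: float = 0.05  # multiplicative lognormal run batch effect
    noise_sd: float = 0.0  # measurement noise on O2 (% air sat)
    body_length_mean: float = 1.5
    body_length_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.true_pcrit < self.o2_start:
            raise ValueError("true_pcrit must lie inside the simulated O2 range")


@dataclass
class SimulatedRespirometry:
    traces: list[OxygenTrace]
    wells: pd.DataFrame
    truth: pd.DataFrame

    def traces_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.traces:
            rows.append(
                pd.DataFrame(
                    {
                        "well_id": tr.well_id,
                        "run_id": tr.run_id,
                        "batch_id": tr.batch_id,
                        "role": tr.role,
                        "time_h": tr.time_h,
                        "o2_percent_airsat": tr.o2,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _decline(t: np.ndarray, o2_0: float, total_rate: float, pcrit: float | None) -> np.ndarray:
    """O2 trajectory: linear at ``total_rate`` until pcrit, then O2-proportional."""
    if total_rate <= 0:
        return np.full_like(t, o2_0)
    o2 = o2_0 - total_rate * t
    if pcrit is None:
        return np.maximum(o2, 0.0)
    below = o2 < pcrit
    if below.any():
        t_c = (o2_0 - pcrit) / total_rate
        k = total_rate / pcrit  # continuity of the decline rate at pcrit
        o2[below] = pcrit * np.exp(-k * (t[below] - t_c))
    return o2


def simulate_traces(config: TraceSimConfig | None = None) -> SimulatedRespirometry:
    """Simulate the full respirometry well layout with a known truth table."""
    config = config or TraceSimConfig()
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration_h + 1e-9, config.dt_min / 60.0)

    clones_by_batch: dict[str, list[str]] = {}
    clone_rate: dict[str, float] = {config.reference_clone: config.rate_mean}
    for b, n in enumerate(config.clones_per_batch, start=1):
        batch = f"B{b}"
        names = []
        for c in range(n):
            name = config.reference_clone if (b == 1 and c == 0) else f"{batch}-CL{c:02d}"
            names.append(name)
            if name not in clone_rate:
                clone_rate[name] = float(
                    max(0.5, rng.normal(config.rate_mean, config.rate_sd))
                )
        clones_by_batch[batch] = names

    traces: list[OxygenTrace] = []
    wells_rows, truth_rows = [], []

    def add_well(well_id, run_id, batch_id, role, animal_rate, clone=None, subpop=None):
        run_mult = run_effects[run_id] if role in ("experimental", "reference") else 1.0
        rate = animal_rate * run_mult
        total = rate + config.diffusion_rate + config.background_rate
        if role == "blank":
            total = config.diffusion_rate + config.background_rate
        elif role == "diffusion_control":
            total = config.diffusion_rate
        pcrit = config.true_pcrit if role in ("experimental", "reference") else None
        o2 = _decline(t, config.o2_start, total, pcrit)
        if config.noise_sd > 0:
            o2 = np.maximum(o2 + rng.normal(0, config.noise_sd, size=o2.shape), 0.0)
        length = (
            float(max(0.5, rng.normal(config.body_length_mean, config.body_length_sd)))
            if role in ("experimental", "reference")
            else None
        )
        traces.append(
            OxygenTrace(
                well_id=well_id, run_id=run_id, batch_id=batch_id, role=role,
                time_h=t.copy(), o2=o2, body_length_mm=length, clone=clone,
                subpopulation=subpop,
            )
        )
        wells_rows.append(
            {"well_id": well_id, "run_id": run_id, "batch_id": batch_id, "role": role,
             "clone": clone, "subpopulation": subpop, "body_length_mm": length}
        )
        reached = bool(pcrit is not None and o2[-1] < pcrit)
        truth_rows.append(
            {"well_id": well_id, "role": role, "clone": clone,
             "true_rate": rate if role in ("experimental", "reference") else 0.0,
             "total_decline_rate": total, "true_pcrit": pcrit,
             "reached_pcrit": reached, "body_length_mm": length}
        )

    run_effects: dict[str, float] = {}
    # sealed no-animal run measuring film diffusion
    for wi in range(config.n_diffusion_wells):
        add_well(f"D-{wi:02d}", "run_diffusion", "B0", "diffusion_control", 0.0)

    run_no = 0
    for b, batch in enumerate(clones_by_batch, start=1):
        subpop = "historical" if b == 1 else "modern"
        for r in range(config.runs_per_batch):
            run_no += 1
            run_id = f"run{run_no:02d}"
            run_effects[run_id] = float(np.exp(rng.normal(0.0, config.run_effect_sd)))
            wi = 0
            for clone in clones_by_batch[batch]:
                add_well(f"{run_id}-W{wi:02d}", run_id, batch, "experimental",
                         clone_rate[clone], clone=clone, subpop=subpop)
                wi += 1
            for _ in range(config.n_reference_wells):
                add_well(f"{run_id}-W{wi:02d}", run_id, batch, "reference",
                         clone_rate[config.reference_clone],
                         clone=config.reference_clone, subpop="historical")
                wi += 1
            for _ in range(config.n_blank_wells):
                add_well(f"{run_id}-W{wi:02d}", run_id, batch, "blank", 0.0)
                wi += 1

    return SimulatedRespirometry(
        traces=traces,
        wells=pd.DataFrame(wells_rows),
        truth=pd.DataFrame(truth_rows),
    )


def simulate_pcrit_profile(
    true_pcrit: float = 25.0,
    n: int = 40,
    sigma: float = 0.05,
    plateau_rate: float = 1.0,
    o2_max: float = 100.0,
    o2_min: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rate-vs-O2 profile: oxyregulating plateau breaking at ``true_pcrit``
    to a conforming segment through the origin, plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    o2 = np.linspace(o2_max, o2_min, n)
    rate = np.where(o2 >= true_pcrit, plateau_rate, plateau_rate * o2 / true_pcrit)
    if sigma > 0:
        rate = rate + rng.normal(0.0, sigma, size=n)
    return o2, rate


# -- time to immobilization ---------------------------------------------------


@dataclass
class TimmSimConfig:
    """T_imm records with run and clone random effects and a subpopulation effect.

    The genetic-cluster composition mirrors the study system: one cluster of
    historical clones, one mixed cluster with clones from both subpopulations,
    and one modern cluster.  Males and egg-bearing females are injected at the
    contamination rates to exercise the exclusion rules.
    """

    n_hist_cluster: int = 5
    n_mixed_hist: int = 6
    n_mixed_modern: int = 3
    n_modern_cluster: int = 9
    runs_per_batch: int = 2
    reps_per_run: int = 3
    grand_mean_s: float = 600.0
    subpop_effect_s: float = -120.0  # modern minus historical
    cluster_effects_s: tuple[float, float, float] = (0.0, 0.0, 0.0)  # historical, mixed, modern
    sigma_run_s: float = 30.0
    sigma_clone_s: float = 60.0
    sigma_residual_s: float = 90.0
    male_rate: float = 0.05
    egg_rate: float = 0.10
    body_length_mean: float = 1.5
    body_length_sd: float = 0.15
    reference_clone: str = "SS4-5"
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.sigma_run_s, self.sigma_clone_s, self.sigma_residual_s):
            if v < 0:
                raise ValueError("variance components must be non-negative")


def simulate_timm(config: TimmSimConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """T_imm records plus a truth dict of all simulated effects."""
    config = config or TimmSimConfig()
    rng = np.random.default_rng(config.seed)

    clones = []
    clones.append((config.reference_clone, "historical", "historical"))
    for c in range(1, config.n_hist_cluster):
        clones.append((f"H{c:02d}", "historical", "historical"))
    for c in range(config.n_mixed_hist):
        clones.append((f"MXH{c:02d}", "historical", "mixed"))
    for c in range(config.n_mixed_modern):
        clones.append((f"MXM{c:02d}", "modern", "mixed"))
    for c in range(config.n_modern_cluster):
        clones.append((f"M{c:02d}", "modern", "modern"))

    order = rng.permutation(len(clones))
    batch_of = {}
    for pos, idx in enumerate(order):
        batch_of[clones[idx][0]] = "B1" if pos % 2 == 0 else "B2"

    n_runs = 2 * config.runs_per_batch
    run_ids = [f"run{r + 1}" for r in range(n_runs)]
    runs_of_batch = {
        "B1": run_ids[: config.runs_per_batch],
        "B2": run_ids[config.runs_per_batch:],
    }
    run_eff = {r: rng.normal(0.0, config.sigma_run_s) for r in run_ids}
    clone_eff = {name: rng.normal(0.0, config.sigma_clone_s) for name, _, _ in clones}
    cluster_effect = dict(zip(("historical", "mixed", "modern"), config.cluster_effects_s))

    rows = []
    for name, subpop, cluster in clones:
        batch = batch_of[name]
        for run in runs_of_batch[batch]:
            for _ in range(config.reps_per_run):
                t = (
                    config.grand_mean_s
                    + (config.subpop_effect_s if subpop == "modern" else 0.0)
                    + cluster_effect[cluster]
                    + run_eff[run]
                    + clone_eff[name]
                    + rng.normal(0.0, config.sigma_residual_s)
                )
                sex = "male" if rng.random() < config.male_rate else "female"
                has_eggs = bool(sex == "female" and rng.random() < config.egg_rate)
                rows.append(
                    {
                        "clone": name,
                        "subpopulation": subpop,
                        "genetic_cluster": cluster,
                        "run": run,
                        "batch": batch,
                        "t_imm": max(t, 1.0),
                        "body_length_mm": float(
                            max(0.5, rng.normal(config.body_length_mean, config.body_length_sd))
                        ),
                        "sex": sex,
                        "has_eggs": has_eggs,
                    }
                )
    df = pd.DataFrame(rows)
    truth = {
        "grand_mean": config.grand_mean_s,
        "subpop_effect": config.subpop_effect_s,
        "cluster_effects": cluster_effect,
        "run_effects": run_eff,
        "clone_effects": clone_eff,
        "sigma_run": config.sigma_run_s,
        "sigma_clone": config.sigma_clone_s,
        "sigma_residual": config.sigma_residual_s,
    }
    return df, truth
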