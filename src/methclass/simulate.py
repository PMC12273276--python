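"""Synthetic metastatic-melanoma cohort generator.

Emulates the statistical structure the analysis pipeline assumes: four
latent methylation classes (DEM < LOW < INT < CIMP) with monotonically
increasing global β driven by a nested CpG-island hypermethylation gradient,
tumor-purity mixing with a fixed normal profile, promoter-β ↔ expression
anticorrelation for a planted set of coupled genes, an immune gene set
over-expressed in LOW, class-dependent exponential survival hazards and
class-dependent stage-progression probabilities.

The *site and gene architecture* (island/open-sea status, which islands are
hypermethylation-prone, promoter coordinates, coupled/immune gene identity)
is drawn from ``architecture_seed`` and is therefore shared by all cohorts
simulated from the same config — mirroring real biology, where CIMP-prone
islands are a property of the genome, not of the cohort.  Per-sample
randomness (class membership, β noise, purity, expression noise, survival)
comes from the ``seed`` argument, so distinct seeds give independent cohorts
from the same population.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import (
    BetaMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    Region,
    RegionMap,
    write_beta_matrix,
    write_expression_matrix,
    write_gmt,
    write_region_bed,
    write_sample_sheet,
)
from .subtypes import CLASS_ORDER


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the reference study conditions."""

    n_samples: int = 160
    n_sites: int = 20_000
    island_fraction: float = 0.3
    n_informative_sites: int = 2_000
    #: mean β over informative island sites per class, strictly increasing
    class_mean_beta: dict = field(
        default_factory=lambda: {"DEM": 0.05, "LOW": 0.15, "INT": 0.35, "CIMP": 0.6}
    )
    #: Beta-distribution concentration (a + b)
    kappa: float = 20.0
    purity_range: tuple = (0.6, 1.0)
    normal_island_beta: float = 0.1
    normal_opensea_beta: float = 0.8
    #: β of a fully hyper-/non-hypermethylated informative island site
    hyper_beta: float = 0.85
    hypo_beta: float = 0.03
    #: width of the per-site susceptibility gradient (smaller = more bimodal)
    gradient_temperature: float = 0.15
    #: sd (logit scale) of class-specific per-site offsets (class DMR
    #: "fingerprints") on top of the shared gradient; gives each class a
    #: reproducible site profile so within-class profiles correlate
    class_fingerprint_sd: float = 2.0
    n_genes: int = 5_000
    n_coupled_genes: int = 500
    sites_per_promoter: int = 3
    coupling_strength: float = 1.0
    coupling_noise_sd: float = 0.75
    n_immune_genes: int = 100
    #: z-unit mean shift of immune genes in the LOW class
    immune_set_effect: float = 1.0
    #: hazard ratios vs LOW baseline (exponential, median 60 months)
    hazard_ratios: dict = field(
        default_factory=lambda: {"DEM": 1.8, "LOW": 1.0, "INT": 2.0, "CIMP": 2.8}
    )
    baseline_median_months: float = 60.0
    #: probability of progressing to a subsequent AJCC stage, per class
    progression_probs: dict = field(
        default_factory=lambda: {"DEM": 0.80, "LOW": 0.62, "INT": 0.75, "CIMP": 0.83}
    )
    #: fraction of progressors whose progression is to CNS (stage IVM1D)
    cns_fraction_of_progressors: dict = field(
        default_factory=lambda: {"DEM": 0.31, "LOW": 0.15, "INT": 0.23, "CIMP": 0.32}
    )
    censor_range: tuple = (1.9, 194.3)
    cohort_tag: str = "SIM"
    architecture_seed: int = 20_240_601

    def validate(self) -> None:
        shifts = [self.class_mean_beta[c] for c in CLASS_ORDER]
        if not all(a < b for a, b in zip(shifts, shifts[1:])):
            raise ValueError("class mean β must be strictly increasing DEM<LOW<INT<CIMP")
        n_island = int(round(self.island_fraction * self.n_sites))
        if self.n_informative_sites > n_island:
            raise ValueError(
                f"n_informative_sites ({self.n_informative_sites}) exceeds island "
                f"sites ({n_island})"
            )
        if self.n_coupled_genes * self.sites_per_promoter > self.n_informative_sites:
            raise ValueError("not enough informative sites for the promoter map")
        for p in (*self.progression_probs.values(),
                  *self.cns_fraction_of_progressors.values()):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for s in shifts:
            if not self.hypo_beta <= s <= self.hyper_beta:
                raise ValueError("class mean β must lie within [hypo_beta, hyper_beta]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("purity_range", "censor_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["purity_range"] = list(self.purity_range)
        d["censor_range"] = list(self.censor_range)
        return d


@dataclass
class GroundTruth:
    """Latent state of a simulated cohort, for validation of the pipeline."""

    classes: pd.Series  # sample_id -> class name
    informative_sites: list
    coupled_genes: list
    immune_genes: list
    promoter_map: RegionMap
    #: true (pre-noise, pure-tumor) mean β per informative site and class
    site_class_means: pd.DataFrame
    #: true promoter mean β per coupled gene and class
    promoter_class_means: pd.DataFrame
    purity: pd.Series


@dataclass
class _Architecture:
    site_ids: list
    island_mask: np.ndarray
    informative_idx: np.ndarray
    mu: np.ndarray  # n_sites x 4 pure-tumor mean β per class
    normal_beta: np.ndarray
    promoter_map: RegionMap
    gene_ids: list
    coupled_genes: list
    immune_genes: list
    promoter_sites: dict  # gene -> list of site indices


def _build_architecture(cfg: SimulationConfig) -> _Architecture:
    rng = np.random.default_rng(cfg.architecture_seed)
    n_prom_sites = cfg.n_coupled_genes * cfg.sites_per_promoter
    n_chr1 = cfg.n_sites - n_prom_sites
    n_island = int(round(cfg.island_fraction * cfg.n_sites))
    n_extra_inf = cfg.n_informative_sites - n_prom_sites

    # chr2 hosts the promoter sites (contiguous triples, tight BED intervals);
    # chr1 hosts everything else at 1 kb spacing.
    chr1_ids = [f"chr1:{1000 * (i + 1)}" for i in range(n_chr1)]
    chr2_ids = []
    promoter_sites: dict[str, list[int]] = {}
    regions = []
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    coupled_genes = gene_ids[: cfg.n_coupled_genes]
    immune_genes = gene_ids[cfg.n_coupled_genes: cfg.n_coupled_genes + cfg.n_immune_genes]
    for g_idx, gene in enumerate(coupled_genes):
        start = 10_000 * (g_idx + 1)
        positions = [start + 100 * j for j in range(cfg.sites_per_promoter)]
        site_idx0 = n_chr1 + g_idx * cfg.sites_per_promoter
        promoter_sites[gene] = list(range(site_idx0, site_idx0 + cfg.sites_per_promoter))
        chr2_ids.extend(f"chr2:{p}" for p in positions)
        regions.append(Region(region_id=f"prom_{gene}", chrom="chr2",
                              start=start, end=positions[-1] + 1))
    site_ids = chr1_ids + chr2_ids

    island_mask = np.zeros(cfg.n_sites, dtype=bool)
    island_mask[n_chr1:] = True  # promoter sites are islands
    chr1_island = rng.choice(n_chr1, size=n_island - n_prom_sites, replace=False)
    island_mask[chr1_island] = True

    informative = np.concatenate([
        rng.choice(chr1_island, size=n_extra_inf, replace=False),
        np.arange(n_chr1, cfg.n_sites),
    ])
    informative = np.sort(informative)

    # Graded hypermethylation gradient with class fingerprints: each
    # informative site gets a susceptibility threshold t_i shared by all
    # classes, plus an independent per-class logit offset (its "fingerprint").
    # The pure-tumor mean at site i in class c is
    #   hypo + span * sigmoid(-t_i/tau + fingerprint_ic + b_c),
    # where the class propensity b_c is solved so the class mean over
    # informative sites equals the configured value exactly.  The shared
    # gradient makes the classes globally ordered; the fingerprints make
    # within-class site profiles heterogeneous, as real class DMRs are.
    n_inf = len(informative)
    t_site = (rng.permutation(n_inf) + 0.5) / n_inf
    mu = np.empty((cfg.n_sites, len(CLASS_ORDER)))
    mu[island_mask] = cfg.normal_island_beta
    mu[~island_mask] = cfg.normal_opensea_beta
    span = cfg.hyper_beta - cfg.hypo_beta
    tau = cfg.gradient_temperature
    fingerprints = rng.normal(0.0, cfg.class_fingerprint_sd,
                              size=(n_inf, len(CLASS_ORDER)))
    for c_idx, cls_name in enumerate(CLASS_ORDER):
        f_c = (cfg.class_mean_beta[cls_name] - cfg.hypo_beta) / span
        x = -t_site / tau + fingerprints[:, c_idx]
        b = brentq(lambda v: expit(x + v).mean() - f_c, -80, 80, xtol=1e-12)
        mu[informative, c_idx] = cfg.hypo_beta + span * expit(x + b)

    normal_beta = np.where(island_mask, cfg.normal_island_beta, cfg.normal_opensea_beta)
    return _Architecture(
        site_ids=site_ids,
        island_mask=island_mask,
        informative_idx=informative,
        mu=mu,
        normal_beta=normal_beta,
        promoter_map=RegionMap(regions),
        gene_ids=gene_ids,
        coupled_genes=coupled_genes,
        immune_genes=immune_genes,
        promoter_sites=promoter_sites,
    )


def simulate_cohort(
    cfg: SimulationConfig, seed: int
) -> tuple[BetaMatrix, ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Draw one cohort; reproducible given (config, seed)."""
    cfg.validate()
    arch = _build_architecture(cfg)
    rng = np.random.default_rng(seed)

    n = cfg.n_samples
    sample_ids = [f"{cfg.cohort_tag}{i:03d}" for i in range(n)]
    # balanced class assignment (n // 4 per class, remainder to the first classes)
    classes = np.array([CLASS_ORDER[i % 4] for i in range(n)])
    class_idx = np.array([CLASS_ORDER.index(c) for c in classes])

    # pure-tumor β ~ Beta(mu*kappa, (1-mu)*kappa), then linear purity mixing
    mu = np.clip(arch.mu[:, class_idx], 1e-3, 1 - 1e-3)  # sites x samples
    a = mu * cfg.kappa
    tumor = rng.beta(a, cfg.kappa - a)
    purity = rng.uniform(*cfg.purity_range, size=n)
    beta = purity[None, :] * tumor + (1 - purity[None, :]) * arch.normal_beta[:, None]
    beta_df = pd.DataFrame(beta, index=arch.site_ids, columns=sample_ids)

    # expression in z-space
    z = rng.normal(size=(cfg.n_genes, n))
    gene_pos = {g: i for i, g in enumerate(arch.gene_ids)}
    for g in arch.immune_genes:
        z[gene_pos[g]] += cfg.immune_set_effect * (classes == "LOW")
    for g in arch.coupled_genes:
        prom_beta = beta[arch.promoter_sites[g], :].mean(axis=0)
        sd = prom_beta.std(ddof=1)
        if sd > 0:
            b_std = (prom_beta - prom_beta.mean()) / sd
            z[gene_pos[g]] = (
                -cfg.coupling_strength * b_std
                + cfg.coupling_noise_sd * rng.normal(size=n)
            )
    expr_df = pd.DataFrame(z, index=arch.gene_ids, columns=sample_ids)

    # survival: exponential with class hazard ratios, administrative censoring
    lam0 = np.log(2) / cfg.baseline_median_months
    hr = np.array([cfg.hazard_ratios[c] for c in classes])
    t_event = rng.exponential(1.0 / (lam0 * hr))
    t_censor = rng.uniform(*cfg.censor_range, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    # stage progression
    prog_p = np.array([cfg.progression_probs[c] for c in classes])
    progression = rng.uniform(size=n) < prog_p
    cns_f = np.array([cfg.cns_fraction_of_progressors[c] for c in classes])
    cns = progression & (rng.uniform(size=n) < cns_f)
    initial = np.where(rng.uniform(size=n) < 0.6, "III", "IV")
    final = initial.copy()
    final[progression & (initial == "III") & ~cns] = "IV"
    final[progression & (initial == "IV") & ~cns] = "IVM1C"
    final[cns] = "IVM1D"

    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": sample_ids,
        "cohort": cfg.cohort_tag,
        "initial_stage": initial,
        "final_stage": final,
        "progression": progression,
        "survival_months": np.round(time, 6),
        "event": event,
        "purity": np.round(purity, 6),
    })

    informative_ids = [arch.site_ids[i] for i in arch.informative_idx]
    site_class_means = pd.DataFrame(
        arch.mu[arch.informative_idx], index=informative_ids, columns=CLASS_ORDER
    )
    promoter_class_means = pd.DataFrame(
        {g: arch.mu[arch.promoter_sites[g], :].mean(axis=0) for g in arch.coupled_genes},
        index=CLASS_ORDER,
    ).T
    truth = GroundTruth(
        classes=pd.Series(classes, index=sample_ids, name="class"),
        informative_sites=informative_ids,
        coupled_genes=list(arch.coupled_genes),
        immune_genes=list(arch.immune_genes),
        promoter_map=arch.promoter_map,
        site_class_means=site_class_means,
        promoter_class_means=promoter_class_means,
        purity=pd.Series(purity, index=sample_ids, name="purity"),
    )
    return (
        BetaMatrix(beta=beta_df),
        ExpressionMatrix(values=expr_df, is_counts=False),
        sheet,
        truth,
    )


def make_fixture_bundle(cfg: SimulationConfig, out_dir: str | Path, seed: int) -> dict:
    """Simulate one cohort and write it in every pipeline input format.

    Returns a dict of paths. Regeneration with the same (config, seed) is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    beta, expr, sheet, truth = simulate_cohort(cfg, seed)
    paths = {
        "beta": out_dir / "beta.tsv",
        "expression": out_dir / "expression.tsv",
        "sample_sheet": out_dir / "sample_sheet.csv",
        "promoters": out_dir / "promoters.bed",
        "signatures": out_dir / "signatures.gmt",
        "truth_labels": out_dir / "truth_labels.tsv",
    }
    write_beta_matrix(beta, paths["beta"])
    write_expression_matrix(expr, paths["expression"])
    write_sample_sheet(sheet, paths["sample_sheet"])
    write_region_bed(truth.promoter_map, paths["promoters"])
    sigs = GeneSetCollection()
    sigs.add("immune_planted", truth.immune_genes)
    sigs.add("coupled_planted", truth.coupled_genes)
    write_gmt(sigs, paths["signatures"])
    truth.classes.to_frame().to_csv(paths["truth_labels"], sep="\t")
    return paths
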