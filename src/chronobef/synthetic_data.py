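"""Synthetic chronosequence studies.

Generates community tables, function proxies and sample metadata with the
statistical structure the downstream analysis assumes: a global survey of
soil chronosequences (sites that share climate, parent material and
vegetation but differ in time since soil formation), five composite
samples per plot, four organism groups sampled to group-specific depths,
and thirteen ecosystem-function proxies whose within-plot coupling to
diversity decays with soil age.

The generative model, per plot and then per sample:

1.  log10(age) is uniform over the design range within each
    chronosequence; climate (MAT, MAP, aridity index) and the
    categorical soil-forming factors are drawn once per chronosequence
    and held fixed.
2.  Latent resources (plant cover, soil organic carbon, microbial
    biomass) are increasing saturating functions of log10(age), scaled
    upward with MAP, with lognormal plot-level heterogeneity and
    sample-level noise proportional to ``noise_sd``.
3.  Each group's richness target increases with log10(age) and
    resources; OTU counts are multinomial draws from a log-series
    rank-abundance profile truncated to the richness target, at a
    per-sample depth at least the group's rarefaction depth.
4.  Function f in sample j is
    ``alpha_f + kappa(plot) * z_div_j + beta_f * z_res_j + eps`` with
    ``kappa(plot) = kappa0 + coupling_slope * log10(age)``, so the
    within-plot diversity-function correlation weakens with age by
    construction.
5.  Two functions ("fungal plant pathogens", "ARG abundance") are
    emitted as positive abundances on an inverted-benefit scale and
    re-oriented downstream.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chronobef.community import DEFAULT_DEPTHS, ORGANISM_GROUPS, OtuTable
from chronobef.functions import DEFAULT_FUNCTIONS, DEFAULT_INVERTED, FunctionMatrix

PARENT_MATERIALS = ("volcanic", "sedimentary", "dunes", "glacier")
VEGETATION_TYPES = ("forest", "shrubland", "grassland", "cropland")
CLIMATE_CLASSES = ("tropical", "temperate", "continental", "polar", "arid")

#: OTU pool size per organism group (kept modest so the full pipeline,
#: including 87 per-plot networks, runs in seconds on one core)
DEFAULT_POOL_SIZES = {
    "invertebrates": 120,
    "protists": 250,
    "fungi": 400,
    "bacteria": 800,
}

#: dominant taxa used for the composition-shift analyses, per group;
#: the first list is favoured at low ranks (abundant, early-soil OTUs),
#: the second at high ranks
_TAXA = {
    "bacteria": (
        ["Actinobacteria", "Firmicutes", "Chloroflexi"],
        ["Proteobacteria", "Acidobacteria", "Bacteroidetes", "Verrucomicrobia"],
    ),
    "fungi": (
        ["Ascomycota", "Chytridiomycota"],
        ["Basidiomycota", "Mortierellomycota", "Glomeromycota"],
    ),
    "protists": (
        ["Cercozoa", "Ochrophyta"],
        ["Ciliophora", "Amoebozoa", "Apicomplexa"],
    ),
    "invertebrates": (
        ["Arthropoda", "Rotifera"],
        ["Annelida", "Nematoda", "Platyhelminthes", "Tardigrada"],
    ),
}


@dataclass
class GroupDesign:
    """OTU pool size and rarefaction depth for one organism group."""

    pool_size: int
    rarefaction_depth: int


def default_groups() -> dict[str, GroupDesign]:
    return {
        g: GroupDesign(DEFAULT_POOL_SIZES[g], DEFAULT_DEPTHS[g])
        for g in ORGANISM_GROUPS
    }


def default_plots_per_chronosequence() -> list[int]:
    # 7 chronosequences of 6 stages + 9 of 5 stages = 87 plots
    return [6] * 7 + [5] * 9


@dataclass
class StudyDesign:
    """Parameters of a synthetic chronosequence survey.

    Defaults reproduce the reference design: 16 chronosequences, 87
    plots, 5 composite samples per plot (435 samples), soil ages from
    10 to 10^7 years, 13 function proxies, and a diversity-function
    coupling that declines by ``coupling_slope`` per decade of soil age.
    """

    n_chronosequences: int = 16
    plots_per_chronosequence: list[int] = field(
        default_factory=default_plots_per_chronosequence
    )
    samples_per_plot: int = 5
    age_range: tuple[float, float] = (10.0, 1e7)
    organism_groups: dict[str, GroupDesign] = field(default_factory=default_groups)
    n_functions: int = 13
    coupling_intercept: float = 0.8
    coupling_slope: float = -0.1
    dryland_coupling_slope: float | None = None
    noise_sd: float = 0.3
    seed: int = 1

    def validate(self) -> None:
        for name in ("coupling_intercept", "coupling_slope", "noise_sd"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"design field {name!r} must be finite, got {v}")
        if self.dryland_coupling_slope is not None and not math.isfinite(
            self.dryland_coupling_slope
        ):
            raise ValueError("design field 'dryland_coupling_slope' must be finite")
        lo, hi = self.age_range
        if not (math.isfinite(lo) and math.isfinite(hi) and 0 < lo < hi):
            raise ValueError(
                f"design field 'age_range' must be finite with 0 < min < max, "
                f"got {self.age_range}"
            )
        if self.n_chronosequences < 1:
            raise ValueError("design field 'n_chronosequences' must be >= 1")
        if len(self.plots_per_chronosequence) != self.n_chronosequences:
            raise ValueError(
                "design field 'plots_per_chronosequence' must have one entry "
                f"per chronosequence ({self.n_chronosequences}), got "
                f"{len(self.plots_per_chronosequence)}"
            )
        if any(p < 2 for p in self.plots_per_chronosequence):
            raise ValueError(
                "design field 'plots_per_chronosequence': every chronosequence "
                "needs >= 2 stages"
            )
        if self.samples_per_plot < 3:
            raise ValueError(
                "design field 'samples_per_plot' must be >= 3 "
                "(rank correlation on fewer is meaningless)"
            )
        if self.noise_sd < 0:
            raise ValueError("design field 'noise_sd' must be nonnegative")
        if self.n_functions < 3:
            raise ValueError("design field 'n_functions' must be >= 3")
        for g, spec in self.organism_groups.items():
            if spec.pool_size < 10 or spec.rarefaction_depth < 10:
                raise ValueError(
                    f"design field 'organism_groups[{g}]' needs pool_size and "
                    "rarefaction_depth >= 10"
                )

    @property
    def n_plots(self) -> int:
        return int(sum(self.plots_per_chronosequence))

    @property
    def n_samples(self) -> int:
        return self.n_plots * self.samples_per_plot


@dataclass
class GeneratedStudy:
    """A synthetic survey: metadata, counts, functions, taxonomy, truth.

    ``truth`` records the generative parameters actually used (per-plot
    coupling, latent resources, per-sample diversity scores) for
    parameter-recovery tests.
    """

    design: StudyDesign
    samples: pd.DataFrame
    otu_tables: dict[str, OtuTable]
    functions: FunctionMatrix
    taxonomy: pd.DataFrame
    truth: dict


def _function_names(n: int) -> tuple[list[str], list[str]]:
    if n == len(DEFAULT_FUNCTIONS):
        return list(DEFAULT_FUNCTIONS), list(DEFAULT_INVERTED)
    names = [f"function_{i + 1:02d}" for i in range(n - 2)]
    inverted = ["fungal_plant_pathogens", "args_abundance"]
    return names + inverted, inverted


def _saturation(logage: np.ndarray | float) -> np.ndarray | float:
    """Increasing, saturating transform of log10(age) into (0, 1)."""
    return logage / (logage + 2.0)


def generate_study(design: StudyDesign | None = None) -> GeneratedStudy:
    """Draw one synthetic chronosequence study. Deterministic given
    ``design.seed``."""
    if design is None:
        design = StudyDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)

    lo10, hi10 = np.log10(design.age_range[0]), np.log10(design.age_range[1])

    # ---- chronosequence-level draws -------------------------------------
    chrono_rows = []
    for c in range(design.n_chronosequences):
        mat = rng.uniform(-5.0, 25.0)
        map_ = rng.uniform(100.0, 3000.0)
        ai = float(np.clip(map_ / 1500.0 * np.exp(rng.normal(0, 0.2)), 0.05, 3.0))
        if ai < 0.5:
            climate = "arid"
        elif mat > 20:
            climate = "tropical"
        elif mat > 10:
            climate = "temperate"
        elif mat > 0:
            climate = "continental"
        else:
            climate = "polar"
        chrono_rows.append(
            dict(
                chronosequence_id=f"cs{c + 1:02d}",
                MAT=mat,
                MAP=map_,
                aridity_index=ai,
                parent_material=PARENT_MATERIALS[rng.integers(len(PARENT_MATERIALS))],
                vegetation_type=VEGETATION_TYPES[rng.integers(len(VEGETATION_TYPES))],
                climate_class=climate,
            )
        )

    # ---- plot-level draws -----------------------------------------------
    plot_rows = []
    for c, n_plots in enumerate(design.plots_per_chronosequence):
        ch = chrono_rows[c]
        logages = np.sort(rng.uniform(lo10, hi10, size=n_plots))
        mapfac = ch["MAP"] / 3000.0
        for p, logage in enumerate(logages):
            sat = _saturation(logage)
            resfac = 0.3 + 0.7 * mapfac
            plot_noise = np.exp(rng.normal(0.0, 0.25, size=3))
            plant_cover = float(np.clip(100.0 * sat * resfac * plot_noise[0], 0.5, 100.0))
            soc = float(8.0 * sat * resfac * plot_noise[1])
            mb = float(400.0 * sat * resfac * plot_noise[2])
            is_dryland = ch["aridity_index"] < 0.5
            slope = (
                design.dryland_coupling_slope
                if (is_dryland and design.dryland_coupling_slope is not None)
                else design.coupling_slope
            )
            kappa = design.coupling_intercept + slope * logage
            plot_rows.append(
                dict(
                    plot_id=f"{ch['chronosequence_id']}_p{p + 1:02d}",
                    chronosequence_id=ch["chronosequence_id"],
                    logage=float(logage),
                    soil_age_years=float(10.0**logage),
                    sat=float(sat),
                    mapfac=float(mapfac),
                    plant_cover=plant_cover,
                    soc=soc,
                    microbial_biomass=mb,
                    kappa=float(kappa),
                    soil_ph=float(
                        np.clip(8.0 - 2.5 * sat - 1.5 * mapfac + rng.normal(0, 0.3), 3.5, 9.0)
                    ),
                    texture_clay_silt=float(
                        np.clip(15.0 + 65.0 * sat + rng.normal(0, 6.0), 5.0, 95.0)
                    ),
                    total_p=float(800.0 * (1.0 - 0.5 * sat) * np.exp(rng.normal(0, 0.2))),
                    salinity=float(
                        0.5 / (ch["aridity_index"] + 0.2) * np.exp(rng.normal(0, 0.3))
                    ),
                    plant_richness=int(rng.poisson(3.0 + 30.0 * sat * mapfac)),
                )
            )
    plots = pd.DataFrame(plot_rows)

    # ---- sample-level draws ---------------------------------------------
    s_per = design.samples_per_plot
    n_samples = design.n_samples
    sample_rows = []
    z_div = np.empty(n_samples)
    res_log = np.empty(n_samples)  # log resource composite, z-scored later
    for i, plot in plots.iterrows():
        ch = chrono_rows[int(plot["chronosequence_id"][2:]) - 1]
        for s in range(s_per):
            j = i * s_per + s
            z_div[j] = rng.normal(0.0, 1.0)
            jitter = np.exp(rng.normal(0.0, 0.5 * design.noise_sd, size=3))
            pc = float(np.clip(plot["plant_cover"] * jitter[0], 0.5, 100.0))
            soc = float(plot["soc"] * jitter[1])
            mb = float(plot["microbial_biomass"] * jitter[2])
            res_log[j] = float(np.mean(np.log([pc, soc, mb])))
            soil_jit = np.exp(rng.normal(0.0, 0.3 * design.noise_sd, size=3))
            sample_rows.append(
                dict(
                    sample_id=f"{plot['plot_id']}_s{s + 1}",
                    plot_id=plot["plot_id"],
                    chronosequence_id=plot["chronosequence_id"],
                    soil_age_years=plot["soil_age_years"],
                    MAT=ch["MAT"],
                    MAP=ch["MAP"],
                    aridity_index=ch["aridity_index"],
                    parent_material=ch["parent_material"],
                    vegetation_type=ch["vegetation_type"],
                    climate_class=ch["climate_class"],
                    soil_ph=float(np.clip(plot["soil_ph"] + rng.normal(0, 0.1), 3.0, 9.5)),
                    texture_clay_silt=float(
                        np.clip(plot["texture_clay_silt"] + rng.normal(0, 2.0), 2.0, 98.0)
                    ),
                    soc=soc,
                    total_n=float(soc * 0.08 * np.exp(rng.normal(0, 0.1))),
                    total_p=float(plot["total_p"] * soil_jit[0]),
                    available_p=float(plot["total_p"] * 0.05 * soil_jit[1]),
                    salinity=float(plot["salinity"] * soil_jit[2]),
                    plant_cover=pc,
                    plant_richness=int(plot["plant_richness"]),
                    microbial_biomass=mb,
                )
            )
    samples = pd.DataFrame(sample_rows)
    sample_ids = samples["sample_id"].to_numpy()
    z_res = (res_log - res_log.mean()) / res_log.std()

    # ---- OTU tables ------------------------------------------------------
    otu_tables: dict[str, OtuTable] = {}
    taxonomy_rows = []
    richness_base = {}
    for group in ORGANISM_GROUPS:
        gspec = design.organism_groups[group]
        pool = gspec.pool_size
        ranks = np.arange(pool)
        # geometric (Motomura) rank-abundance: one-parameter control of
        # evenness, mild enough that deep ranks remain detectable at the
        # group's rarefaction depth (so richness is read out with
        # age-independent fidelity)
        x = 1.0 - 1.5 / pool
        base_probs = x ** ranks
        otu_ids = [f"{group[:4]}_otu{k + 1:04d}" for k in range(pool)]

        # taxon labels: low ranks favour the early-soil taxa list
        early, late = _TAXA[group]
        for k in range(pool):
            w_late = k / max(pool - 1, 1)
            if rng.random() < 0.15:
                taxon = "Other"
            elif rng.random() < w_late:
                taxon = late[rng.integers(len(late))]
            else:
                taxon = early[rng.integers(len(early))]
            taxonomy_rows.append(dict(otu_id=otu_ids[k], group=group, taxon=taxon))

        counts = np.zeros((pool, n_samples), dtype=np.int64)
        rb = np.empty(len(plots))
        for i, plot in plots.iterrows():
            probs_plot = base_probs * np.exp(rng.normal(0.0, 0.4, size=pool))
            # near-linear growth in log10(age), modestly boosted by MAP, so
            # the age signal dominates between-chronosequence climate noise
            rb[i] = pool * (0.18 + 0.055 * plot["logage"]) * (0.95 + 0.10 * plot["mapfac"])
            for s in range(s_per):
                j = i * s_per + s
                target = int(np.clip(round(rb[i] * (1.0 + 0.12 * z_div[j])), 5, pool))
                p = probs_plot[:target] / probs_plot[:target].sum()
                depth = int(round(gspec.rarefaction_depth * rng.uniform(1.3, 1.8)))
                counts[:target, j] = rng.multinomial(depth, p)
        richness_base[group] = rb.tolist()
        otu_tables[group] = OtuTable(
            counts=pd.DataFrame(counts, index=otu_ids, columns=sample_ids),
            group=group,
            rarefaction_depth=gspec.rarefaction_depth,
        )

    # ---- function proxies ------------------------------------------------
    names, inverted = _function_names(design.n_functions)
    alpha = rng.uniform(2.0, 6.0, size=design.n_functions)
    beta = rng.uniform(0.2, 0.5, size=design.n_functions)
    kappa_sample = np.repeat(plots["kappa"].to_numpy(), s_per)
    fvals = np.empty((design.n_functions, n_samples))
    for f in range(design.n_functions):
        eps = rng.normal(0.0, design.noise_sd, size=n_samples)
        benefit = alpha[f] + kappa_sample * z_div + beta[f] * z_res + eps
        if names[f] in inverted:
            # emitted as a positive abundance, higher = worse
            fvals[f] = np.exp(-(benefit - alpha[f]))
        else:
            fvals[f] = benefit
    orientation = {n: ("invert" if n in inverted else "benefit") for n in names}
    functions = FunctionMatrix(
        values=pd.DataFrame(fvals, index=names, columns=sample_ids),
        orientation=orientation,
    )

    truth = dict(
        seed=design.seed,
        coupling_intercept=design.coupling_intercept,
        coupling_slope=design.coupling_slope,
        plot_id=plots["plot_id"].tolist(),
        plot_logage=plots["logage"].tolist(),
        plot_kappa=plots["kappa"].tolist(),
        plot_plant_cover=plots["plant_cover"].tolist(),
        plot_soc=plots["soc"].tolist(),
        plot_microbial_biomass=plots["microbial_biomass"].tolist(),
        richness_base=richness_base,
        sample_id=list(map(str, sample_ids)),
        z_diversity=z_div.tolist(),
        z_resources=z_res.tolist(),
        alpha=alpha.tolist(),
        beta=beta.tolist(),
    )

    return GeneratedStudy(
        design=design,
        samples=samples,
        otu_tables=otu_tables,
        functions=functions,
        taxonomy=pd.DataFrame(taxonomy_rows),
        truth=truth,
    )


def write_study(study: GeneratedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a study as TSV files plus truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "samples.tsv"
    study.samples.to_csv(p, sep="\t", index=False)
    paths["samples"] = p

    for group, table in study.otu_tables.items():
        p = outdir / f"{group}_otu.tsv"
        table.counts.to_csv(p, sep="\t", index_label="otu_id")
        paths[f"{group}_otu"] = p

    p = outdir / "functions.tsv"
    study.functions.values.to_csv(p, sep="\t", index_label="function")
    paths["functions"] = p

    p = outdir / "taxonomy.tsv"
    study.taxonomy.to_csv(p, sep="\t", index=False)
    paths["taxonomy"] = p

    p = outdir / "truth.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(study.truth, fh, indent=1)
    paths["truth"] = p
    return paths
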