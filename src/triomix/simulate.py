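"""Synthetic paired multi-omics cohorts with known planted effects.

The generator emulates the post-QC matrices the statistical pipeline
consumes: CpG beta values with patient effects and planted contiguous
DMRs, negative-binomial read counts with patient effects and planted
log2 fold-changes, and protein abundances with planted shifts and
per-sample missingness. A :class:`TruthSet` records every injection so
downstream callers can be scored for recall, precision and empirical FDR.

Beta values are generated additively on the logit scale (logit-normal
noise keeps the [0, 1] support and a baseline mixture near logit(0.1)
and logit(0.9) mimics 450k bimodality). Counts follow a gamma-Poisson
(NB2) scheme with Var = mu + phi * mu^2. Protein effects are injected on
the log2 scale to match the rule-based differential-abundance call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as tio

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "Annotation",
    "Cohort",
    "generate_annotation",
    "generate_cohort",
    "generate_replication",
    "write_cohort",
]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic paired cohort.

    Defaults mirror the discovery design being emulated (12 patients,
    each contributing one intact and one degraded sample) at a
    desk-scale feature universe: 20,000 CpG probes standing in for the
    425,694 post-QC array probes, 2,000 genes for the 15,418 post-QC
    genes, 500 proteins. Planted effect sizes are the recovery
    conditions exercised by the test-suite: |log2FC| = 1.5 for DE genes,
    delta-beta = 0.15 for DMRs, |log2| = 1.0 for proteins.
    """

    n_patients: int = 12
    n_probes: int = 20_000
    n_genes: int = 2_000
    n_proteins: int = 500
    n_de_genes: int = 300
    de_log2fc: float = 1.5
    n_dmrs: int = 40
    dmr_probe_count: int = 5
    dmr_delta_beta: float = 0.15
    n_diff_proteins: int = 50
    protein_effect_log2: float = 1.0
    protein_missing_rate: float = 0.2
    nb_dispersion: float = 0.1
    patient_sd: float = 0.3
    beta_noise_sd: float = 0.2
    protein_noise_sd: float = 0.35
    lib_size: float = 1_000_000.0
    n_concordant: int = 10
    replication_attenuation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients for paired statistics")
        if not 0 <= self.protein_missing_rate < 1:
            raise ValueError("protein_missing_rate must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 < self.replication_attenuation <= 1:
            raise ValueError("replication_attenuation must be in (0, 1]")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if self.n_diff_proteins > self.n_proteins:
            raise ValueError("n_diff_proteins exceeds n_proteins")
        if self.n_concordant > min(self.n_de_genes, self.n_dmrs, self.n_diff_proteins) and (
            self.n_de_genes or self.n_dmrs or self.n_diff_proteins
        ):
            if self.n_concordant > 0:
                raise ValueError(
                    "n_concordant must not exceed any planted-effect count"
                )
        if self.dmr_probe_count < 3:
            raise ValueError("dmr_probe_count must be >= 3 to form a callable region")
        if not 0 <= self.dmr_delta_beta < 0.35:
            raise ValueError("dmr_delta_beta must be in [0, 0.35) to stay inside (0,1)")


@dataclass
class TruthSet:
    """Record of every planted effect, exactly as injected."""

    de_genes: dict[str, float] = field(default_factory=dict)
    dmrs: list[dict] = field(default_factory=list)
    diff_proteins: dict[str, float] = field(default_factory=dict)
    concordant_genes: list[str] = field(default_factory=list)

    @property
    def dmr_probe_deltas(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for d in self.dmrs:
            for pid in d["probe_ids"]:
                out[pid] = d["delta_beta"]
        return out

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Annotation:
    manifest: pd.DataFrame
    gene_models: pd.DataFrame
    promoter_map: dict[str, list[str]]


@dataclass
class Cohort:
    config: SimulationConfig
    sheet: tio.SampleSheet
    beta: pd.DataFrame
    counts: pd.DataFrame
    proteins: pd.DataFrame
    annotation: Annotation
    truth: TruthSet


_GENES_PER_CHROM = 100


def generate_annotation(config: SimulationConfig, rng: np.random.Generator | None = None) -> Annotation:
    """Tile genes on synthetic chromosomes and place probes around them.

    Half the probes land in promoters (within 1,000 bp upstream of the
    TSS, strand-aware, so that a gene's promoter probes always satisfy
    the 1 kb adjacency rule), 35% in gene bodies and the rest in
    intergenic space kept clear of any gene territory.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_genes, n_probes = config.n_genes, config.n_probes

    gene_rows = []
    chrom_genes: dict[str, list[int]] = {}
    for g in range(n_genes):
        chrom = f"chr{g // _GENES_PER_CHROM + 1}"
        idx_on_chrom = g % _GENES_PER_CHROM
        if idx_on_chrom == 0:
            cursor = 10_000
        length = int(rng.integers(2_000, 10_001))
        start = cursor
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        cursor = end + int(rng.integers(5_000, 15_001))
        gene_rows.append((chrom, start, end, f"G{g + 1:05d}", 0, strand, length))
        chrom_genes.setdefault(chrom, []).append(g)
    gene_models = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "gene_id", "score", "strand", "length"]
    )

    probe_rows: list[tuple] = []  # (chrom, pos, gene, feature)
    promoter_positions: dict[str, list[int]] = {}
    if n_probes > 0 and n_genes > 0:
        prom_total = int(round(0.5 * n_probes))
        body_total = int(round(0.35 * n_probes))
        inter_total = n_probes - prom_total - body_total
        prom_k = rng.multinomial(prom_total, np.full(n_genes, 1.0 / n_genes))
        body_k = rng.multinomial(body_total, np.full(n_genes, 1.0 / n_genes))

        for g in range(n_genes):
            chrom, start, end, gid, _, strand, _ = gene_rows[g]
            k = int(prom_k[g])
            if k:
                base = np.linspace(50, 950, k) if k > 1 else np.array([50.0])
                offsets = np.clip(base + rng.integers(-20, 21, size=k), 1, 999).astype(int)
                offsets = np.unique(offsets)
                for off in offsets:
                    pos = (start - off) if strand == "+" else (end - 1 + off)
                    feature = "TSS200" if off <= 200 else "TSS1500"
                    probe_rows.append((chrom, int(pos), gid, feature))
                promoter_positions[gid] = list(offsets)
            for _ in range(int(body_k[g])):
                pos = int(rng.integers(start, end))
                probe_rows.append((chrom, pos, gid, "Body"))

        # intergenic probes: rejection-sample positions clear of gene
        # territories (gene span plus 1.6 kb on both sides)
        chrom_names = sorted(chrom_genes, key=lambda c: int(c[3:]))
        spans = {
            c: [(gene_rows[g][1] - 1_600, gene_rows[g][2] + 1_600) for g in chrom_genes[c]]
            for c in chrom_names
        }
        extents = {c: max(e for _, e in spans[c]) + 20_000 for c in chrom_names}
        placed = 0
        attempts = 0
        while placed < inter_total and attempts < 200 * max(inter_total, 1):
            attempts += 1
            c = chrom_names[int(rng.integers(len(chrom_names)))]
            pos = int(rng.integers(0, extents[c]))
            if any(s <= pos < e for s, e in spans[c]):
                continue
            probe_rows.append((c, pos, "", "intergenic"))
            placed += 1

    manifest = pd.DataFrame(probe_rows, columns=["chrom", "pos", "gene", "feature"])
    if len(manifest):
        key = manifest["chrom"].str.removeprefix("chr").astype(int)
        manifest = manifest.assign(_k=key).sort_values(["_k", "pos"], kind="mergesort")
        manifest = manifest.drop(columns="_k").reset_index(drop=True)
    manifest.insert(0, "probe_id", [f"cg{i + 1:07d}" for i in range(len(manifest))])

    promoter_map: dict[str, list[str]] = {}
    prom_mask = manifest["feature"].isin(["TSS200", "TSS1500"])
    for gid, grp in manifest[prom_mask].groupby("gene"):
        promoter_map[gid] = list(grp["probe_id"])
    return Annotation(manifest, gene_models, promoter_map)


def _make_sheet(patient_prefix: str, n_patients: int, cohort: str) -> tio.SampleSheet:
    rows = []
    for i in range(1, n_patients + 1):
        pid = f"{patient_prefix}{i:03d}"
        rows.append((f"{pid}_I", pid, "intact", cohort))
        rows.append((f"{pid}_D", pid, "degraded", cohort))
    return tio.SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "patient_id", "status", "cohort"])
    )


def _simulate_beta(
    manifest: pd.DataFrame,
    sheet: tio.SampleSheet,
    probe_delta_beta: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
    attenuation: float = 1.0,
) -> pd.DataFrame:
    """Logit-additive beta matrix with planted per-probe delta-beta shifts.

    Planted probes get a mid-range baseline so the logit shift realises
    the requested beta-scale difference at that baseline.
    """
    probes = manifest["probe_id"].to_numpy()
    n_p = len(probes)
    samples = sheet.sample_ids
    status = sheet.table.set_index("sample_id").loc[samples, "status"].to_numpy()
    patients = sheet.table.set_index("sample_id").loc[samples, "patient_id"].to_numpy()
    pat_index = {p: i for i, p in enumerate(pd.unique(patients))}

    planted = np.array([p in probe_delta_beta for p in probes])
    baseline_beta = np.empty(n_p)
    baseline_beta[planted] = rng.uniform(0.35, 0.65, size=int(planted.sum()))
    hyper = rng.random(n_p) < 0.5
    base_logit = np.where(hyper, logit(0.1), logit(0.9)) + rng.normal(0, 0.5, n_p)
    baseline_beta[~planted] = expit(base_logit[~planted])

    delta = np.array([probe_delta_beta.get(p, 0.0) for p in probes]) * attenuation
    target = np.clip(baseline_beta + delta, 0.02, 0.98)
    delta_logit = logit(target) - logit(baseline_beta)

    n_pat = len(pat_index)
    pat_eff = rng.normal(0, config.patient_sd, size=(n_p, n_pat))
    values = np.empty((n_p, len(samples)))
    for j, s in enumerate(samples):
        is_deg = 1.0 if status[j] == "degraded" else 0.0
        eta = (
            logit(baseline_beta)
            + pat_eff[:, pat_index[patients[j]]]
            + is_deg * delta_logit
            + rng.normal(0, config.beta_noise_sd, n_p)
        )
        values[:, j] = expit(eta)
    return pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)


def _simulate_counts(
    gene_models: pd.DataFrame,
    sheet: tio.SampleSheet,
    gene_lfc: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
    attenuation: float = 1.0,
) -> pd.DataFrame:
    genes = gene_models["gene_id"].to_numpy()
    samples = sheet.sample_ids
    status = sheet.table.set_index("sample_id").loc[samples, "status"].to_numpy()
    patients = sheet.table.set_index("sample_id").loc[samples, "patient_id"].to_numpy()
    pat_factors = {
        p: float(np.exp(rng.normal(0, config.patient_sd))) for p in pd.unique(patients)
    }
    rate = np.exp(rng.normal(0, 1.0, size=len(genes)))
    rate /= rate.sum()
    lfc = np.array([gene_lfc.get(g, 0.0) for g in genes]) * attenuation

    phi = config.nb_dispersion
    values = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j in range(len(samples)):
        is_deg = 1.0 if status[j] == "degraded" else 0.0
        mu = config.lib_size * rate * pat_factors[patients[j]] * np.exp2(is_deg * lfc)
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        else:
            lam = mu
        values[:, j] = rng.poisson(lam)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)


def _simulate_proteins(
    protein_ids: list[str],
    sheet: tio.SampleSheet,
    protein_effect: dict[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    samples = sheet.sample_ids
    status = sheet.table.set_index("sample_id").loc[samples, "status"].to_numpy()
    patients = sheet.table.set_index("sample_id").loc[samples, "patient_id"].to_numpy()
    n_p = len(protein_ids)
    base = rng.uniform(10, 20, size=n_p)
    effect = np.array([protein_effect.get(p, 0.0) for p in protein_ids])
    pat_index = {p: i for i, p in enumerate(pd.unique(patients))}
    pat_eff = rng.normal(0, config.patient_sd, size=(n_p, len(pat_index)))
    log2_ab = np.empty((n_p, len(samples)))
    for j in range(len(samples)):
        is_deg = 1.0 if status[j] == "degraded" else 0.0
        log2_ab[:, j] = (
            base
            + pat_eff[:, pat_index[patients[j]]]
            + is_deg * effect
            + rng.normal(0, config.protein_noise_sd, n_p)
        )
    values = np.exp2(log2_ab)
    missing = rng.random(values.shape) < config.protein_missing_rate
    values[missing] = np.nan
    return pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"), columns=samples)


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full discovery cohort with planted, recorded effects.

    A configurable subset of planted DE genes (``n_concordant``) also
    receives a promoter DMR with sign-opposed delta-beta and a protein
    effect with the same sign as the expression change, emulating
    genes dysregulated concordantly across all three omics levels.
    """
    rng = np.random.default_rng(config.seed)
    ann = generate_annotation(config, rng)
    manifest, gene_models = ann.manifest, ann.gene_models
    genes = list(gene_models["gene_id"])

    eligible = sorted(
        g for g, probes in ann.promoter_map.items() if len(probes) >= config.dmr_probe_count
    )
    if config.n_dmrs > len(eligible):
        raise ValueError(
            f"probe density incompatible with gene count: only {len(eligible)} genes "
            f"have >= {config.dmr_probe_count} promoter probes, need {config.n_dmrs}"
        )

    concordant = (
        sorted(rng.choice(eligible, size=config.n_concordant, replace=False))
        if config.n_concordant
        else []
    )
    sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in concordant}

    remaining_genes = [g for g in genes if g not in set(concordant)]
    extra_de = list(
        rng.choice(remaining_genes, size=config.n_de_genes - len(concordant), replace=False)
    )
    de_genes = {g: sign[g] * config.de_log2fc for g in concordant}
    for g in extra_de:
        de_genes[g] = (1.0 if rng.random() < 0.5 else -1.0) * config.de_log2fc

    remaining_eligible = [g for g in eligible if g not in set(concordant)]
    extra_dmr = list(
        rng.choice(remaining_eligible, size=config.n_dmrs - len(concordant), replace=False)
    )
    dmr_genes = {g: -sign[g] * config.dmr_delta_beta for g in concordant}
    for g in extra_dmr:
        dmr_genes[g] = (1.0 if rng.random() < 0.5 else -1.0) * config.dmr_delta_beta

    manifest_pos = manifest.set_index("probe_id")
    dmrs = []
    for g, delta in dmr_genes.items():
        members = ann.promoter_map[g][: config.dmr_probe_count]
        pos = manifest_pos.loc[members, "pos"]
        dmrs.append(
            {
                "chrom": manifest_pos.loc[members[0], "chrom"],
                "start": int(pos.min()),
                "end": int(pos.max()) + 1,
                "probe_ids": list(members),
                "delta_beta": float(delta),
                "gene": g,
            }
        )

    non_conc_genes = [g for g in genes if g not in set(concordant)]
    protein_rest = list(
        rng.choice(non_conc_genes, size=config.n_proteins - len(concordant), replace=False)
    )
    protein_ids = sorted(set(concordant) | set(protein_rest))
    diff_proteins = {g: sign[g] * config.protein_effect_log2 for g in concordant}
    rest_pool = [p for p in protein_ids if p not in diff_proteins]
    extra_prot = list(
        rng.choice(rest_pool, size=config.n_diff_proteins - len(concordant), replace=False)
    )
    for p in extra_prot:
        diff_proteins[p] = (1.0 if rng.random() < 0.5 else -1.0) * config.protein_effect_log2

    truth = TruthSet(
        de_genes={g: float(v) for g, v in de_genes.items()},
        dmrs=dmrs,
        diff_proteins={p: float(v) for p, v in diff_proteins.items()},
        concordant_genes=list(concordant),
    )

    sheet = _make_sheet("P", config.n_patients, "discovery")
    beta = _simulate_beta(manifest, sheet, truth.dmr_probe_deltas, config, rng)
    counts = _simulate_counts(gene_models, sheet, truth.de_genes, config, rng)
    proteins = _simulate_proteins(protein_ids, sheet, truth.diff_proteins, config, rng)
    logger.info(
        "simulated cohort: %d patients, %d probes, %d genes, %d proteins; planted "
        "%d DE genes, %d DMRs, %d differential proteins (%d concordant)",
        config.n_patients, len(manifest), len(genes), len(protein_ids),
        len(de_genes), len(dmrs), len(diff_proteins), len(concordant),
    )
    return Cohort(config, sheet, beta, counts, proteins, ann, truth)


def generate_replication(
    config: SimulationConfig,
    annotation: Annotation,
    truth: TruthSet,
    n_patients_rep: int,
    cohort: str = "replication_knee",
    seed: int | None = None,
) -> tuple[tio.SampleSheet, pd.DataFrame, pd.DataFrame]:
    """Replication cohort: new patients, same planted effects attenuated.

    Every planted effect keeps its discovery sign and is multiplied by
    ``config.replication_attenuation``, so direction concordance holds in
    expectation while magnitudes shrink.
    """
    if n_patients_rep < 2:
        raise ValueError("paired statistics need at least 2 replication patients")
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(seed)
    prefix = {"replication_knee": "RK", "replication_hip": "RH"}.get(cohort, "R")
    sheet = _make_sheet(prefix, n_patients_rep, cohort)
    beta = _simulate_beta(
        annotation.manifest, sheet, truth.dmr_probe_deltas, config, rng,
        attenuation=config.replication_attenuation,
    )
    counts = _simulate_counts(
        annotation.gene_models, sheet, truth.de_genes, config, rng,
        attenuation=config.replication_attenuation,
    )
    return sheet, beta, counts


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write all cohort matrices, annotation and the truth JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_sample_sheet(cohort.sheet, out / "samples.csv")
    tio.write_matrix(cohort.beta, out / "beta.tsv")
    tio.write_matrix(cohort.counts, out / "counts.tsv")
    tio.write_matrix(cohort.proteins, out / "proteins.tsv")
    tio.write_probe_manifest(cohort.annotation.manifest, out / "probes.tsv")
    tio.write_gene_models(cohort.annotation.gene_models, out / "genes.bed")
    cohort.truth.to_json(out / "truth.json")
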