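"""Readers/writers for the pipeline's interchange formats and the orchestrator.

All tabular interchange is TSV (UTF-8, tab, '.' decimal) with samples as rows
and taxa as columns; index reads are 4-line FASTQ with Phred+33 qualities
(via Biopython); every pipeline stage writes a JSON manifest recording its
inputs, parameters, seed and output checksums so a run is resumable and
auditable stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import TableParseError

FIRE_LEVELS = {"burnt", "unburnt"}
SUBSTRATE_LEVELS = {"litter", "soil"}
PINE_LEVELS = {"near", "away"}
META_COLUMNS = ("plot", "pair", "fire", "substrate", "pine")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_count_table(path) -> pd.DataFrame:
    """Samples-by-taxa integer count table; duplicate ids and bad cells rejected."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise TableParseError(f"duplicate sample id(s): {dup}")
    if df.columns.duplicated().any():
        raise TableParseError("duplicate taxon columns")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise TableParseError(f"non-count cell at row {row!r}, column {col!r}")
        df[col] = vals.astype(np.int64)
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata with validated factor levels (case-normalized with warning)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id",) + META_COLUMNS if c not in meta.columns]
    if missing:
        raise TableParseError(f"metadata missing column(s): {missing}")
    for col, levels in (("fire", FIRE_LEVELS), ("substrate", SUBSTRATE_LEVELS), ("pine", PINE_LEVELS)):
        vals = meta[col].astype(str)
        lowered = vals.str.lower().str.strip()
        if (lowered != vals).any():
            warnings.warn(f"normalized case/whitespace in metadata column {col!r}")
        unknown = set(lowered) - levels
        if unknown:
            raise ValueError(f"unknown {col} level(s): {sorted(unknown)}")
        meta[col] = lowered
    lonely = meta["pair"].value_counts()
    lonely = lonely[lonely == 1]
    if len(lonely):
        warnings.warn(f"pair(s) with a single member: {list(lonely.index)}")
    return meta


def write_taxonomy_records(tax: pd.DataFrame, path, ranks=("kingdom", "phylum", "class", "order", "family", "genus")) -> None:
    """Per-database taxonomy TSV: esv_id then label:confidence per rank."""
    out = pd.DataFrame({"esv_id": tax["esv_id"]})
    for r in ranks:
        conf = tax[f"{r}_conf"] if f"{r}_conf" in tax.columns else pd.Series(1.0, index=tax.index)
        out[r] = tax[r].astype(str) + ":" + conf.map(lambda c: f"{float(c):.3f}")
    out.to_csv(path, sep="\t", index=False)


def read_taxonomy_records(path, ranks=("kingdom", "phylum", "class", "order", "family", "genus")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = pd.DataFrame({"esv_id": df["esv_id"]})
    for r in ranks:
        split = df[r].str.rsplit(":", n=1, expand=True)
        out[r] = split[0].fillna("")
        out[f"{r}_conf"] = pd.to_numeric(split[1], errors="coerce").fillna(0.0)
    return out


# ---------------------------------------------------------------------------
# FASTQ index reads and barcode maps
# ---------------------------------------------------------------------------

def write_index_fastq(reads: pd.DataFrame, path, which: int = 1) -> None:
    """Write index reads (I1 or I2) as 4-line Phred+33 FASTQ."""
    records = []
    for _, r in reads.iterrows():
        rec = SeqRecord(Seq(r[f"index{which}"]), id=r["read_id"], description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r[f"qual{which}"]]
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_index_fastq(i1_path, i2_path=None) -> pd.DataFrame:
    def _load(p, which):
        rows = []
        for rec in SeqIO.parse(str(p), "fastq"):
            rows.append(
                {
                    "read_id": rec.id,
                    f"index{which}": str(rec.seq),
                    f"qual{which}": "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    ),
                }
            )
        return pd.DataFrame(rows)

    reads = _load(i1_path, 1)
    if i2_path is not None:
        reads = reads.merge(_load(i2_path, 2), on="read_id", validate="1:1")
    return reads


def read_barcode_map(path) -> pd.DataFrame:
    bc = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in bc.columns or "index1" not in bc.columns:
        raise TableParseError("barcode map needs sample_id and index1 columns")
    return bc


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    outdir: str = "firecomm_run"
    seed: int = 1
    n_pairs: int = 30
    pine_split: float = 0.5
    drop_one: bool = True
    n_index_reads: int = 20_000
    per_base_error: float = 0.005
    demux_threshold: float = 6.0
    rare_threshold: float = 1e-5
    conf_threshold: float = 0.80
    pearson_cap: float = 4.0
    rank: str = "family"
    n_perm: int = 999
    include_pine: bool = False
    stages: tuple = (
        "simulate", "demux", "filter", "taxonomy", "normalize",
        "ordinate", "influential", "diversity",
    )
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        return cfg

    def validate(self) -> None:
        if not 0 < self.rare_threshold < 1:
            raise ValueError("rare_threshold outside (0, 1)")
        if not 0 <= self.conf_threshold <= 1:
            raise ValueError("conf_threshold outside [0, 1]")
        if self.pearson_cap <= 0 or self.n_perm < 1:
            raise ValueError("pearson_cap must be > 0 and n_perm >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))


def _stage_done(outdir: Path, stage: str) -> bool:
    mf = outdir / f"manifest_{stage}.json"
    if not mf.exists():
        return False
    manifest = json.loads(mf.read_text())
    for name, digest in manifest["outputs"].items():
        p = outdir / name
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Run the synthetic end-to-end pipeline, one manifest per stage.

    Stage order: simulate -> demux -> filter -> taxonomy (consensus +
    aggregation) -> normalize -> ordinate -> influential -> diversity.
    Every stage is deterministic given the config seed; with ``resume=True``
    stages whose manifests verify are skipped.
    """
    from . import demux as dmx
    from . import diversity as dv
    from . import influential as infl
    from . import normalize as norm
    from . import ordination as ord_
    from . import simulate as sim
    from . import taxonomy as tax

    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    def _log(stage, msg):
        print(f"[firecomm:{stage}] {msg}", file=sys.stderr)

    # ---- simulate ---------------------------------------------------------
    if "simulate" in config.stages and not (resume and _stage_done(out, "simulate")):
        design = sim.generate_design(config.n_pairs, config.pine_split, seed, config.drop_one)
        spec = sim.EffectSpec.study_default()
        counts, taxmap, truth = sim.generate_counts(design, spec, seed)
        barcodes = sim.make_barcodes(design["sample_id"], seed=seed)
        reads, read_truth = sim.generate_index_reads(
            design, barcodes, config.per_base_error, config.n_index_reads, seed
        )
        write_metadata(design, out / "metadata.tsv")
        write_count_table(counts, out / "esv_counts.tsv")
        taxmap.to_csv(out / "taxonomy_map.tsv", sep="\t", index=False)
        barcodes.to_csv(out / "barcodes.tsv", sep="\t", index=False)
        write_index_fastq(reads, out / "index_I1.fastq")
        read_truth.to_csv(out / "read_truth.tsv", sep="\t", index=False)
        primary, secondary = make_database_records(taxmap, seed)
        write_taxonomy_records(primary, out / "taxonomy_primary.tsv")
        write_taxonomy_records(secondary, out / "taxonomy_secondary.tsv")
        truth["family_labels"].to_frame().to_csv(out / "truth_labels.tsv", sep="\t")
        (out / "truth.json").write_text(
            json.dumps({"family_labels": truth["family_labels"].to_dict()}, indent=2)
        )
        _write_manifest(out, "simulate", {"seed": seed, "n_pairs": config.n_pairs},
                        sorted(out.glob("*.tsv")) + sorted(out.glob("*.fastq")))
        _log("simulate", f"{len(design)} samples, {counts.shape[1]} ESVs")

    design = read_metadata(out / "metadata.tsv")

    # ---- demux ------------------------------------------------------------
    if "demux" in config.stages and not (resume and _stage_done(out, "demux")):
        reads = read_index_fastq(out / "index_I1.fastq")
        barcodes = read_barcode_map(out / "barcodes.tsv")
        assign = dmx.assign_reads(reads, barcodes, config.demux_threshold)
        assign.to_csv(out / "demux_assignments.tsv", sep="\t", index=False)
        _write_manifest(out, "demux", {"threshold": config.demux_threshold},
                        [out / "demux_assignments.tsv"])
        _log("demux", f"{(assign['assigned_sample'] != '').mean():.1%} reads assigned")

    # ---- filter -----------------------------------------------------------
    if "filter" in config.stages and not (resume and _stage_done(out, "filter")):
        counts = read_count_table(out / "esv_counts.tsv")
        filtered, cutoff = tax.filter_rare_esvs(counts, config.rare_threshold)
        write_count_table(filtered, out / "esv_counts_filtered.tsv")
        _write_manifest(out, "filter", {"rel_threshold": config.rare_threshold, "cutoff": cutoff},
                        [out / "esv_counts_filtered.tsv"])
        _log("filter", f"cutoff {cutoff}: {counts.shape[1]} -> {filtered.shape[1]} ESVs")

    # ---- taxonomy (consensus + aggregate) ---------------------------------
    if "taxonomy" in config.stages and not (resume and _stage_done(out, "taxonomy")):
        filtered = read_count_table(out / "esv_counts_filtered.tsv")
        primary = read_taxonomy_records(out / "taxonomy_primary.tsv")
        secondary = read_taxonomy_records(out / "taxonomy_secondary.tsv")
        primary = primary[primary["esv_id"].isin(filtered.columns)]
        secondary = secondary[secondary["esv_id"].isin(filtered.columns)]
        consensus = tax.consensus_table(primary, secondary, config.conf_threshold)
        consensus.to_csv(out / "taxonomy_consensus.tsv", sep="\t", index=False)
        rank_tab, dropped = tax.aggregate_by_rank(filtered, consensus, config.rank)
        write_count_table(rank_tab, out / f"{config.rank}_counts.tsv")
        _write_manifest(out, "taxonomy",
                        {"conf_threshold": config.conf_threshold, "rank": config.rank,
                         "dropped_reads": dropped},
                        [out / "taxonomy_consensus.tsv", out / f"{config.rank}_counts.tsv"])
        _log("taxonomy", f"{rank_tab.shape[1]} taxa at {config.rank}; {dropped} reads dropped")

    # ---- normalize --------------------------------------------------------
    if "normalize" in config.stages and not (resume and _stage_done(out, "normalize")):
        rank_tab = read_count_table(out / f"{config.rank}_counts.tsv")
        cells = design.set_index("sample_id").loc[rank_tab.index]
        groups = cells["fire"].str.cat(cells["substrate"], sep="-")
        adj, shrink_log = norm.group_variance_standardize(rank_tab, groups, config.pearson_cap)
        scaled, factors = norm.geometric_mean_scale(adj)
        scaled.to_csv(out / f"{config.rank}_relabund.tsv", sep="\t", index_label="sample_id")
        factors.to_frame().to_csv(out / "scale_factors.tsv", sep="\t")
        shrink_log.to_csv(out / "shrink_log.tsv", sep="\t", index=False)
        _write_manifest(out, "normalize", {"pearson_cap": config.pearson_cap},
                        [out / f"{config.rank}_relabund.tsv", out / "scale_factors.tsv",
                         out / "shrink_log.tsv"])
        _log("normalize", f"{len(shrink_log)} counts shrunk")

    # ---- ordinate ---------------------------------------------------------
    if "ordinate" in config.stages and not (resume and _stage_done(out, "ordinate")):
        relabund = pd.read_csv(out / f"{config.rank}_relabund.tsv", sep="\t", index_col=0)
        meta = design.set_index("sample_id").loc[relabund.index].reset_index()
        H = ord_.hellinger(relabund)
        cond = ord_.condition_matrix(meta)
        terms = ord_.treatment_terms(meta, include_pine=config.include_pine)
        res = ord_.partial_rda(H, terms, cond)
        fr = res.fractions
        frac_rows = [
            {"component": "conditional", "fraction": fr["conditional"]},
            {"component": "constrained_total", "fraction": fr["constrained_total"]},
            {"component": "residual", "fraction": fr["residual"]},
        ] + [{"component": f"term:{t}", "fraction": v} for t, v in fr["by_term"].items()]
        pd.DataFrame(frac_rows).to_csv(out / "variance_fractions.tsv", sep="\t", index=False)
        res.site_scores["taxa"].to_csv(out / "site_scores.tsv", sep="\t")
        res.taxon_scores["taxa"].to_csv(out / "taxon_scores.tsv", sep="\t")
        pd.DataFrame({"eigenvalue": res.eigenvalues}).to_csv(out / "eigenvalues.tsv", sep="\t", index=False)
        tests = []
        for t in terms:
            f, (df1, df2), p = ord_.marginal_permutation_test(
                H, terms, t, cond, config.n_perm, seed
            )
            tests.append({"term": t, "F": f, "df1": df1, "df2": df2, "p": p})
        pd.DataFrame(tests).to_csv(out / "marginal_tests.tsv", sep="\t", index=False)
        (out / "ordination_manifest.json").write_text(json.dumps(
            {"seed": seed, "n_perm": config.n_perm,
             "condition": "pair indicators", "scaling": "taxon-focused"}, indent=2))
        _write_manifest(out, "ordinate", {"n_perm": config.n_perm},
                        [out / "variance_fractions.tsv", out / "site_scores.tsv",
                         out / "taxon_scores.tsv", out / "marginal_tests.tsv"])
        _log("ordinate", f"constrained {fr['constrained_total']:.1%}, "
                         f"conditional {fr['conditional']:.1%}")

    # ---- influential ------------------------------------------------------
    if "influential" in config.stages and not (resume and _stage_done(out, "influential")):
        relabund = pd.read_csv(out / f"{config.rank}_relabund.tsv", sep="\t", index_col=0)
        meta = design.set_index("sample_id").loc[relabund.index].reset_index()
        H = ord_.hellinger(relabund)
        cond = ord_.condition_matrix(meta)
        terms = ord_.treatment_terms(meta, include_pine=config.include_pine)
        res = ord_.partial_rda(H, terms, cond)
        cent = infl.interaction_centroids(res, meta)
        thr = infl.influential_threshold(cent)
        selected, dist = infl.select_influential(res.taxon_scores["taxa"].iloc[:, :2], thr)
        report = dist.to_frame()
        report["selected"] = report.index.isin(selected)
        report["threshold"] = thr
        report.to_csv(out / "influential_report.tsv", sep="\t")
        if selected:
            fit = infl.fit_tweedie_interaction(relabund, meta, selected)
            contrasts = infl.treatment_contrasts(fit, seed=seed)
            labels = infl.classify_specialists(fit.cell_means, contrasts)
            contrasts.to_csv(out / "contrast_table.tsv", sep="\t", index=False)
            fit.tests.to_csv(out / "tweedie_tests.tsv", sep="\t")
            labels.to_frame().to_csv(out / "specialist_labels.tsv", sep="\t")
            np.log2(fit.cell_means).to_csv(out / "heatmap_matrix.tsv", sep="\t")
        _write_manifest(out, "influential", {"threshold": thr, "n_selected": len(selected)},
                        [out / "influential_report.tsv"])
        _log("influential", f"{len(selected)} families above threshold {thr:.3f}")

    # ---- diversity --------------------------------------------------------
    if "diversity" in config.stages and not (resume and _stage_done(out, "diversity")):
        rank_tab = read_count_table(out / f"{config.rank}_counts.tsv")
        meta = design.set_index("sample_id").loc[rank_tab.index].reset_index()
        div = dv.diversity_table(rank_tab)
        div.to_csv(out / "diversity.tsv", sep="\t")
        rich = dv.fit_richness_glmm(div["richness"], meta)
        even = dv.fit_evenness_glmm(div["evenness"], meta)
        model_tab = rich.tests[["chi2", "p"]].add_prefix("richness_").join(
            even.tests[["chi2", "p"]].add_prefix("evenness_")
        )
        model_tab.to_csv(out / "diversity_glmm_tests.tsv", sep="\t")
        H = ord_.hellinger(rank_tab)
        groups = meta["fire"].str.cat(meta["substrate"], sep="-").to_numpy()
        f_p, df_p, p_p = dv.permanova(H, groups, config.n_perm, seed)
        f_d, df_d, p_d = dv.dispersion_homogeneity(H, groups, config.n_perm, seed)
        pd.DataFrame(
            [
                {"test": "permanova", "F": f_p, "df1": df_p[0], "df2": df_p[1], "p": p_p},
                {"test": "dispersion", "F": f_d, "df1": df_d[0], "df2": df_d[1], "p": p_d},
            ]
        ).to_csv(out / "beta_diversity_tests.tsv", sep="\t", index=False)
        _write_manifest(out, "diversity", {"n_perm": config.n_perm},
                        [out / "diversity.tsv", out / "diversity_glmm_tests.tsv",
                         out / "beta_diversity_tests.tsv"])
        _log("diversity", f"PERMANOVA F={f_p:.1f} (p={p_p:.3f}); dispersion F={f_d:.2f} (p={p_d:.3f})")

    return out


def make_database_records(taxmap: pd.DataFrame, seed: int, agree_frac: float = 0.9):
    """Synthetic primary/secondary database records from a true taxonomy map.

    The primary record carries the true lineage at high bootstrap confidence;
    the secondary agrees at genus for ``agree_frac`` of ESVs and disagrees
    (triggering the confidence fallback) for the rest, for which the primary
    genus confidence is dropped below the 0.80 rule so assignment truncates at
    family.
    """
    from ._rng import stage_rng

    rng = stage_rng(seed, "db_records")
    n = len(taxmap)
    agree = rng.random(n) < agree_frac
    primary = taxmap.copy()
    for r in ("kingdom", "phylum", "class", "order", "family", "genus"):
        primary[f"{r}_conf"] = np.round(rng.uniform(0.9, 1.0, n), 3)
    primary.loc[~agree, "genus_conf"] = np.round(rng.uniform(0.2, 0.7, (~agree).sum()), 3)
    secondary = taxmap.copy()
    secondary.loc[~agree, "genus"] = secondary.loc[~agree, "genus"] + "_alt"
    for r in ("kingdom", "phylum", "class", "order", "family", "genus"):
        secondary[f"{r}_conf"] = np.round(rng.uniform(0.7, 1.0, n), 3)
    return primary, secondary
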