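"""End-to-end orchestration: simulate -> recruit -> consensus -> abundance,
plus the MAG-collection operon/consensus analysis.

Every run is deterministic in its seed; outputs carry provenance headers
(tool version, seed, config hash) and the summary reconciles counts across
stages (library size >= recruited hits >= consensus-retained hits = sum of
per-taxon counts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import AbundanceRecord, build_abundance_table, fit_layers
from .consensus import (
    PhylotypeCount,
    call_nifh_genes,
    call_positive_mags,
    filter_conflicting_hits,
    select_phylotypes,
)
from .operon import detect_nif_clusters, feature_symbol, find_repeats, flag_retroelement
from .recruit import AlignerParams, recruit_library
from .synthgen import NOVEL_KEY, ReferencePanel, SeriesConfig, simulate_series

UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    config: str  # packaged series config name or YAML path
    seed: int
    outdir: str | None = None
    evalue_max: float = 1e-20
    identity_min: float = 95.0
    phylotype_min: int = 50
    gap_max: int = 2000
    flank: int = 5000
    min_repeat_len: int = 20
    write_reads: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.identity_min <= 100:
            raise ValidationError("identity_min must be in (0, 100]")
        if self.evalue_max <= 0:
            raise ValidationError("evalue_max must be positive")
        if self.phylotype_min < 0 or self.gap_max <= 0 or self.min_repeat_len <= 0:
            raise ValidationError("thresholds must be positive")

    def aligner_params(self) -> AlignerParams:
        return AlignerParams(evalue_max=self.evalue_max, identity_min=self.identity_min)


def _config_hash(cfg_name: str) -> str:
    from importlib import resources as importlib_resources

    path = Path(cfg_name)
    if path.exists():
        text = path.read_text()
    else:
        text = (
            importlib_resources.files("diazoscan.resources.configs") / f"{cfg_name}.yaml"
        ).read_text()
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_series(run_cfg: RunConfig) -> dict:
    """Run the read-level pipeline on one sample-series config.

    Returns a summary dict with the per-sample abundance table, per-layer
    quadratic fits, hypolimnion phylotype selection and the unclassified
    fraction of nifH-assigned reads.
    """
    try:
        cfg = SeriesConfig.from_yaml(run_cfg.config)
    except Exception as e:  # noqa: BLE001
        raise StageError("config", e) from e

    panel = ReferencePanel(run_cfg.seed)
    try:
        series = simulate_series(cfg, run_cfg.seed, panel)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    tiers = panel.tiers()
    params = run_cfg.aligner_params()
    calls = call_nifh_genes(panel.annotations())

    records: list[AbundanceRecord] = []
    all_hits_rows: list[dict] = []
    excluded_total = 0
    tier_hits = {1: 0, 2: 0}
    unclassified_hits = 0
    total_retained = 0

    for sample in series.samples:
        if sample.reads is None:
            # counts-only mode: the generated counts stand in for recruitment
            per_taxon = {
                (UNCLASSIFIED if k == NOVEL_KEY else k): v
                for k, v in sample.truth_counts.items()
            }
            retained_n = sum(per_taxon.values())
        else:
            try:
                hits, _summary = recruit_library(sample.reads, tiers, params)
            except Exception as e:  # noqa: BLE001
                raise StageError("recruit", e) from e
            retained, excluded, _non_nif = filter_conflicting_hits(hits, calls)
            excluded_total += excluded
            per_taxon: dict[str, int] = {}
            for h in retained:
                taxon = h.taxon if h.taxon is not None else UNCLASSIFIED
                per_taxon[taxon] = per_taxon.get(taxon, 0) + 1
                tier_hits[h.tier] += 1
                all_hits_rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "read_id": h.read_id,
                        "gene_id": h.gene_id,
                        "taxon": taxon,
                        "tier": h.tier,
                        "identity": round(h.identity, 2),
                        "evalue": h.evalue,
                    }
                )
            retained_n = len(retained)
        unclassified_hits += per_taxon.get(UNCLASSIFIED, 0)
        total_retained += retained_n
        records.append(
            AbundanceRecord(
                sample_id=sample.sample_id,
                date=sample.date,
                layer=sample.layer,
                nifh_hits=retained_n,
                library_size=sample.library_size,
                per_taxon=per_taxon,
            )
        )

    env = series.env if not series.env.empty else None
    table = build_abundance_table(records, env)
    fits = fit_layers(table) if env is not None else {}

    hypo_counts: dict[str, int] = {}
    for rec in records:
        if "hypo" in rec.layer.lower():
            for taxon, n in rec.per_taxon.items():
                if taxon != UNCLASSIFIED:
                    hypo_counts[taxon] = hypo_counts.get(taxon, 0) + n
    selected = select_phylotypes(
        [PhylotypeCount(t, n) for t, n in hypo_counts.items()],
        threshold=run_cfg.phylotype_min,
    )

    max_freq = {
        layer: float(sub["frequency_pct"].max())
        for layer, sub in table.groupby("layer")
    }
    summary = {
        "config": cfg.name,
        "config_hash": _config_hash(run_cfg.config),
        "version": __version__,
        "seed": int(run_cfg.seed),
        "n_samples": len(records),
        "total_nifh_hits": total_retained,
        "excluded_conflicted_hits": excluded_total,
        "hits_per_tier": tier_hits,
        "max_frequency_pct": max_freq,
        "fits": {
            layer: {
                "a": f.a,
                "b": f.b,
                "c": f.c,
                "vertex": f.vertex,
                "is_maximum": f.is_maximum,
                "rss": f.rss,
                "n": f.n,
            }
            for layer, f in fits.items()
        },
        "hypolimnion_phylotype_counts": dict(sorted(hypo_counts.items())),
        "selected_phylotypes": [c.taxon for c in selected],
        "unclassified_pct_of_nifh": (
            100.0 * unclassified_hits / total_retained if total_retained else 0.0
        ),
        "samples": table.to_dict(orient="records"),
    }

    if run_cfg.outdir:
        _write_outputs(run_cfg, cfg, series, table, all_hits_rows, summary)
    return summary


def _provenance(run_cfg: RunConfig, cfg_name: str) -> str:
    return (
        f"# diazoscan {__version__} seed={run_cfg.seed} config={cfg_name} "
        f"sha256={_config_hash(run_cfg.config)}\n"
    )


def _write_outputs(run_cfg, cfg, series, table, hits_rows, summary) -> None:
    out = Path(run_cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance(run_cfg, cfg.name)
    with open(out / "abundance.tsv", "w") as fh:
        fh.write(header)
        table.to_csv(fh, sep="\t", index=False)
    if hits_rows:
        with open(out / "hits.tsv", "w") as fh:
            fh.write(header)
            pd.DataFrame(hits_rows).to_csv(fh, sep="\t", index=False)
    if not series.env.empty:
        with open(out / "env.tsv", "w") as fh:
            fh.write(header)
            series.env.to_csv(fh, sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(series.truth, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    if run_cfg.write_reads:
        from .io_formats import write_fasta

        reads_dir = out / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sample in series.samples:
            if sample.reads is not None:
                write_fasta(dict(sample.reads), reads_dir / f"{sample.sample_id}.fasta")


# ---------------------------------------------------------------------------
# MAG collection analysis

def analyze_mags(
    genomes,
    identity_min: float = 95.0,
    gap_max: int = 2000,
    flank: int = 5000,
    min_repeat_len: int = 20,
) -> dict:
    """Operon detection + consensus MAG calling over a genome collection.

    A genome is Mo-complete when one detected cluster classifies as Mo and
    contains a three-system consensus nifH gene supported at >= 95% identity.
    """
    per_genome = []
    mo_complete: list[str] = []
    annotations = {g.genome_id: g.annotations for g in genomes}
    evidence = {
        g.genome_id: {
            str(r.gene_id): float(r.identity_pct)
            for r in g.annotations.itertuples(index=False)
            if pd.notna(r.identity_pct)
        }
        for g in genomes
    }
    positives = call_positive_mags(annotations, evidence, identity_min=identity_min)

    for g in genomes:
        calls = {c.gene_id: c.status for c in call_nifh_genes(g.annotations)}
        clusters = detect_nif_clusters(g.table, gap_max=gap_max)
        cluster_rows = []
        is_mo_complete = False
        has_retro = False
        for cl in clusters:
            retro = None
            if any("transcriptase" in f.product for f in cl.members) or any(
                "transcriptase" in f.product for f in g.table
            ):
                repeats = find_repeats(
                    g.sequence, (cl.start, cl.end), flank=flank, min_len=min_repeat_len
                )
                retro = flag_retroelement(cl, g.table, repeats)
                has_retro = has_retro or retro.verdict
            consensus_ok = any(
                calls.get(f.gene_id) == "consensus_nifH"
                and evidence[g.genome_id].get(f.gene_id, 0.0) >= identity_min
                and feature_symbol(f) == "nifH"
                for f in cl.members
            )
            if cl.type_label == "Mo" and consensus_ok:
                is_mo_complete = True
            cluster_rows.append(
                {
                    "span": [cl.start, cl.end],
                    "type": cl.type_label,
                    "n_members": len(cl.members),
                    "strand_consensus": cl.strand_consensus,
                    "retroelement": bool(retro.verdict) if retro else False,
                }
            )
        if is_mo_complete:
            mo_complete.append(g.genome_id)
        per_genome.append(
            {
                "genome_id": g.genome_id,
                "lineage": g.lineage,
                "clusters": cluster_rows,
                "mo_complete": is_mo_complete,
                "retroelement": has_retro,
            }
        )
    return {
        "genomes": per_genome,
        "nitrogenase_positive": positives,
        "mo_complete": sorted(mo_complete),
        "n_mo_complete": len(mo_complete),
    }
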