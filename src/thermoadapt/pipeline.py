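"""End-to-end orchestration of the analysis on a matrix + sample sheet.

``analyze`` runs: global normalization -> replicate averaging -> condition
dendrogram -> correlation matrix -> PCA (top-loaded genes, growth
correlation when rates are present) -> enrichment (binomial on PC gene
lists, ranked on the heat-shock contrast) -> per-strain epistasis
regressions, and writes one TSV per stage plus a machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import average_replicates, global_normalize
from .comparative import cluster_profiles, correlation_matrix
from .enrichment import binomial_enrichment, ranked_enrichment, results_table
from .epistasis import responsiveness_alignment, strain_epistasis
from .io import write_matrix
from .pca import pc_growth_correlation, run_pca, top_loaded_genes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Analysis parameters and provenance for one pipeline run."""

    ancestor: str = "Anc"
    linkage: str = "average"
    distance: str = "pearson"
    n_components: int = 4
    tail_fraction: float = 0.05
    n_perm: int = 1000
    alpha: float = 0.001
    min_set_size: int = 16
    seed: int = 0
    skip_enrichment: bool = False
    extras: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> list[str]:
    return [f"thermoadapt {__version__}", f"config_hash={config.config_hash()}",
            f"seed={config.seed}"]


def analyze(matrix: pd.DataFrame, meta: pd.DataFrame,
            genesets: dict[str, list[str]] | None = None,
            config: RunConfig | None = None,
            outdir: str | Path | None = None) -> dict:
    """Run the full analysis; optionally write per-stage TSVs to ``outdir``.

    Returns a bundle with profiles, the dendrogram (Newick), the correlation
    matrix, the PCA result, enrichment tables, per-strain epistasis rows and
    a JSON-ready summary.  A stage failure raises, after a marker file
    naming the stage is written next to any partial outputs.
    """
    config = config or RunConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    bundle: dict = {"config": config}
    stage = "setup"

    def fail_marker(exc: Exception) -> None:
        if out is not None:
            (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")

    try:
        stage = "normalize"
        normalized = global_normalize(matrix)
        logger.info("normalize: %d genes x %d arrays", *normalized.shape)
        if out is not None:
            write_matrix(normalized, out / "normalized.tsv", header)

        stage = "average"
        profiles = average_replicates(normalized, meta)
        bundle["profiles"] = profiles
        logger.info("average: %d profiles", profiles.shape[1])
        if out is not None:
            write_matrix(profiles, out / "profiles.tsv", header)

        stage = "cluster"
        tree = cluster_profiles(profiles, distance=config.distance,
                                linkage=config.linkage)
        bundle["dendrogram"] = tree
        bundle["newick"] = tree.to_newick()
        if out is not None:
            (out / "dendrogram.nwk").write_text(bundle["newick"] + "\n")

        stage = "correlation"
        corr = correlation_matrix(profiles)
        bundle["correlations"] = corr
        if out is not None:
            write_matrix(corr, out / "correlations.tsv", header)

        stage = "pca"
        k = min(config.n_components, profiles.shape[1] - 1)
        pca = run_pca(profiles, n_components=None)
        bundle["pca"] = pca
        top_genes = {c: top_loaded_genes(pca, c, config.tail_fraction)
                     for c in pca.loadings.columns[:k]}
        bundle["top_genes"] = top_genes
        rates = meta.set_index("sample_id")["growth_rate"] if "growth_rate" in meta else None
        growth_r = None
        if rates is not None and rates.notna().all():
            arrays_pca = run_pca(normalized, n_components=None)
            bundle["pca_arrays"] = arrays_pca
            growth_r = pc_growth_correlation(arrays_pca, meta, "PC1")
        bundle["pc1_growth_r"] = growth_r
        if out is not None:
            write_matrix(pca.loadings, out / "pca_loadings.tsv", header)
            write_matrix(pca.scores.T, out / "pca_scores.tsv", header)
            pca.variance_fraction.to_frame().to_csv(out / "pca_variance.tsv", sep="\t")
            for comp, genes in top_genes.items():
                (out / f"top_genes_{comp}.txt").write_text("\n".join(genes) + "\n")

        strains = [s for s in meta["strain"].unique() if s != config.ancestor]

        if config.skip_enrichment or not genesets:
            bundle["enrichment"] = None
            logger.info("enrichment: skipped")
        else:
            stage = "enrichment"
            universe = list(profiles.index)
            binom_tables = {}
            for comp, genes in top_genes.items():
                res = binomial_enrichment(genes, genesets, universe,
                                          alpha=config.alpha,
                                          min_size=config.min_set_size)
                binom_tables[comp] = results_table(res)
            ranked_tables = {}
            anc = config.ancestor
            if f"{anc}_hs" in profiles.columns:
                delta = profiles[f"{anc}_hs"] - profiles[f"{anc}_r"]
                res = ranked_enrichment(delta, genesets, n_perm=config.n_perm,
                                        min_size=config.min_set_size,
                                        seed=config.seed)
                ranked_tables["dHS_A"] = results_table(res)
            bundle["enrichment"] = {"binomial": binom_tables, "ranked": ranked_tables}
            if out is not None:
                for comp, table in binom_tables.items():
                    table.to_csv(out / f"enrichment_binomial_{comp}.tsv",
                                 sep="\t", index=False)
                for name, table in ranked_tables.items():
                    table.to_csv(out / f"enrichment_ranked_{name}.tsv",
                                 sep="\t", index=False)

        stage = "epistasis"
        rows = []
        for strain in strains:
            res = strain_epistasis(profiles, strain, ancestor=config.ancestor)
            rows.append(res.__dict__)
        epi = pd.DataFrame(rows)
        bundle["epistasis"] = epi
        alignments = {}
        for strain in strains:
            if f"{strain}_e" in profiles.columns:
                alignments[strain] = responsiveness_alignment(
                    profiles, strain, ancestor=config.ancestor)
        bundle["alignment"] = alignments
        if out is not None:
            epi.to_csv(out / "epistasis.tsv", sep="\t", index=False)

        stage = "summary"
        summary = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_genes": int(matrix.shape[0]),
            "n_arrays": int(matrix.shape[1]),
            "n_profiles": int(profiles.shape[1]),
            "variance_fraction": pca.variance_fraction.round(10).to_dict(),
            "pc1_growth_r": growth_r,
            "epistasis": epi.round(10).to_dict(orient="records"),
            "alignment": {k: round(v, 10) for k, v in alignments.items()},
            "enrichment_skipped": bool(config.skip_enrichment or not genesets),
        }
        bundle["summary"] = summary
        if out is not None:
            (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                         sort_keys=True) + "\n")
    except Exception as exc:  # noqa: BLE001 - marker then re-raise with stage
        fail_marker(exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle
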