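"""End-to-end orchestration: validate a config, run stages, write artifacts.

The pipeline mirrors the analysis shape of a gene-family selection
study: branch-model fits and LRT, site-level tests and summaries,
physicochemical DAPC of selected sites, synteny scoring/naming,
expression normalization, and motif scanning. Every stage writes plain
TSV/CSV/JSON artifacts and the run manifest records seeds, thresholds
and input hashes so reruns are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as expr_mod
from . import motifs as motifs_mod
from . import physchem, simulate, synteny
from .alignment import read_codon_fasta, write_codon_fasta
from .codon_model import fit_m0, fit_two_ratio, likelihood_ratio_test
from .phylo import read_newick, write_newick
from .site_tests import (
    busted_gene_test,
    fel_site_test,
    meme_site_test,
    slac_site_counts,
    summarize_selected_sites,
)

log = logging.getLogger("hifevol")

ALL_STAGES = [
    "simulate", "branch_test", "site_tests", "physchem",
    "synteny", "expression", "motifs",
]


class ConfigError(ValueError):
    def __init__(self, failures: list[str]):
        self.failures = failures
        super().__init__("invalid config:\n" + "\n".join(f"- {f}" for f in failures))


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    site_p_threshold: float = 0.05
    er_threshold: float = 2.0
    variance_retained: float = 0.8
    inputs: dict[str, str] = field(default_factory=dict)
    simulate_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = raw.get("thresholds", {})
        return cls(
            output_dir=Path(raw.get("output_dir", "hifevol_out")),
            seed=int(raw.get("seed", 1)),
            stages=list(raw.get("stages", ALL_STAGES)),
            site_p_threshold=float(thresholds.get("site_p", 0.05)),
            er_threshold=float(thresholds.get("er", 2.0)),
            variance_retained=float(thresholds.get("variance_retained", 0.8)),
            inputs={k: str(v) for k, v in (raw.get("inputs") or {}).items()},
            simulate_params=dict(raw.get("simulate") or {}),
        )

    def validate(self) -> None:
        failures = []
        for stage in self.stages:
            if stage not in ALL_STAGES:
                failures.append(f"unknown stage {stage!r}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                failures.append(f"input {key!r}: missing file {path}")
        if not 0 < self.site_p_threshold < 1:
            failures.append("thresholds.site_p must be in (0, 1)")
        if failures:
            raise ConfigError(failures)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest (also written)."""
    config.validate()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed
    manifest: dict = {
        "seed": rng_seed,
        "thresholds": {
            "site_p": config.site_p_threshold,
            "er": config.er_threshold,
            "variance_retained": config.variance_retained,
        },
        "stages": [],
        "inputs": {k: _sha256(Path(v)) for k, v in config.inputs.items()},
        "artifacts": [],
    }

    def artifact(name: str) -> Path:
        manifest["artifacts"].append(name)
        return out / name

    aln = tree = None
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            if stage == "simulate":
                aln, tree = _stage_simulate(config, artifact)
            elif stage == "branch_test":
                aln, tree = _load_aln_tree(config, aln, tree)
                _stage_branch_test(config, aln, tree, artifact)
            elif stage == "site_tests":
                aln, tree = _load_aln_tree(config, aln, tree)
                _stage_site_tests(config, aln, tree, artifact)
            elif stage == "physchem":
                aln, tree = _load_aln_tree(config, aln, tree)
                _stage_physchem(config, aln, artifact)
            elif stage == "synteny":
                _stage_synteny(config, artifact)
            elif stage == "expression":
                _stage_expression(config, artifact)
            elif stage == "motifs":
                aln, tree = _load_aln_tree(config, aln, tree)
                _stage_motifs(config, aln, artifact)
            dt = time.perf_counter() - t0
            log.info("stage %s: done in %.1fs", stage, dt)
            manifest["stages"].append(stage)
    except Exception:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_aln_tree(config, aln, tree):
    if aln is not None:
        return aln, tree
    if "alignment" not in config.inputs or "tree" not in config.inputs:
        raise ConfigError(
            ["alignment/tree inputs required when the simulate stage is off"]
        )
    aln = read_codon_fasta(config.inputs["alignment"])
    tree = read_newick(Path(config.inputs["tree"]).read_text())
    return aln, tree


def _stage_simulate(config, artifact):
    p = config.simulate_params
    tree = simulate.random_tree(
        n_taxa=int(p.get("n_taxa", 12)),
        seed=config.seed,
        branch_length_range=tuple(p.get("branch_length_range", (0.05, 0.35))),
    )
    # flag one clade foreground for the branch test
    internal = [i for i in range(1, tree.n_nodes) if tree.children[i]]
    if internal:
        stack = [internal[0]]
        while stack:
            v = stack.pop()
            tree.foreground[v] = True
            stack.extend(tree.children[v])
    scenario = simulate.SimulationScenario(
        tree=tree,
        n_codons=int(p.get("n_codons", 120)),
        kappa=float(p.get("kappa", 2.0)),
        omega_regime=p.get("omega_regime", {"type": "constant", "omega": 0.2}),
        seed=config.seed + 1,
    )
    aln, truth = simulate.simulate_codon_alignment(scenario)
    write_codon_fasta(aln, artifact("simulated_alignment.fasta"))
    artifact("simulated_tree.nwk").write_text(write_newick(tree) + "\n")
    truth.pop("episodic_branch_sets", None)
    artifact("simulation_truth.json").write_text(json.dumps(truth, indent=2))
    return aln, tree


def _stage_branch_test(config, aln, tree, artifact):
    m0 = fit_m0(aln, tree, seed=config.seed, n_starts=1)
    rows = [
        {
            "model": "M0", "minus_lnL": -m0.lnL,
            "kappa": m0.params.kappa,
            "omega": m0.params.omega_map["all"],
            "lrt_p": "",
        }
    ]
    if tree.foreground.any() and not tree.foreground[1:].all():
        two = fit_two_ratio(aln, tree, seed=config.seed, n_starts=1)
        lrt = likelihood_ratio_test(m0, two, df=1)
        rows.append(
            {
                "model": "two-ratio", "minus_lnL": -two.lnL,
                "kappa": two.params.kappa,
                "omega": (
                    f"w0={two.params.omega_map['background']:.4f},"
                    f"w1={two.params.omega_map['foreground']:.4f}"
                ),
                "lrt_p": lrt.p_value,
            }
        )
    pd.DataFrame(rows).to_csv(artifact("branch_models.tsv"), sep="\t", index=False)


def _stage_site_tests(config, aln, tree, artifact):
    fit = fit_m0(aln, tree, seed=config.seed, n_starts=1)
    fel = [fel_site_test(aln, tree, s, fit, config.site_p_threshold)
           for s in range(1, aln.length_codons + 1)]
    meme = [meme_site_test(aln, tree, s, fit, config.site_p_threshold)
            for s in range(1, aln.length_codons + 1)]
    slac = slac_site_counts(aln, tree, fit)
    busted = busted_gene_test(aln, tree, fit)
    rows = []
    for r in fel + meme:
        rows.append(
            {
                "site": r.site, "test": r.test, "alpha": r.alpha,
                "beta": r.beta if r.beta is not None else "",
                "beta_minus": r.beta_minus if r.beta_minus is not None else "",
                "beta_plus": r.beta_plus if r.beta_plus is not None else "",
                "weight_plus": r.weight_plus if r.weight_plus is not None else "",
                "lrt": r.lrt_statistic, "p": r.p_value,
                "er": (busted.evidence_ratios[r.site - 1]
                       if busted.evidence_ratios is not None else ""),
                "call": r.classification,
            }
        )
    pd.DataFrame(rows).to_csv(artifact("site_tests.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "site": c.site, "syn": c.observed_syn, "nonsyn": c.observed_nonsyn,
                "expected_syn_fraction": c.expected_syn_fraction,
                "p_positive": c.p_positive, "p_negative": c.p_negative,
            }
            for c in slac
        ]
    ).to_csv(artifact("slac_counts.tsv"), sep="\t", index=False)
    summary = summarize_selected_sites(
        {"gene": {"meme": meme, "fel": fel, "busted": busted}},
        p_threshold=config.site_p_threshold,
        er_threshold=config.er_threshold,
    )["gene"]
    artifact("site_summary.json").write_text(
        json.dumps(
            {
                "meme_sites": summary.meme_sites,
                "fel_sites": summary.fel_sites,
                "both": summary.both,
                "meme_with_er_support": summary.meme_with_er_support,
                "busted_p": busted.p_value,
            },
            indent=2,
        )
    )


def _stage_physchem(config, aln, artifact):
    summary_path = config.output_dir / "site_summary.json"
    if summary_path.exists():
        sites = json.loads(summary_path.read_text())["meme_sites"]
    else:
        sites = []
    msa = aln.to_protein()
    if not sites:  # fall back to all variable columns
        sites = [
            s for s in range(1, aln.length_codons + 1)
            if len({r[s - 1] for r in msa.values()} - {"-"}) > 1
        ][:20]
    if not sites:
        return
    zm = physchem.encode_zmatrix(msa, sites)
    pd.DataFrame(zm.values, index=zm.taxa, columns=zm.columns).to_csv(
        artifact("zmatrix.csv")
    )
    if len(zm.taxa) >= 3:
        k, bic = physchem.select_k(zm, seed=config.seed)
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=max(k, 2), n_init=10, random_state=config.seed)
        labels = [f"g{c}" for c in km.fit_predict(zm.values)]
        res = physchem.dapc(zm, labels,
                            variance_retained=config.variance_retained)
        pd.DataFrame(
            res.discriminant_axes, index=zm.taxa,
            columns=[f"LD{i + 1}" for i in range(res.discriminant_axes.shape[1])],
        ).to_csv(artifact("dapc_coords.csv"))
        pd.DataFrame(
            res.memberships, index=zm.taxa, columns=res.groups
        ).to_csv(artifact("dapc_membership.tsv"), sep="\t")
        artifact("kmeans_bic.json").write_text(
            json.dumps({"chosen_k": k, "bic": bic}, indent=2)
        )


def _stage_synteny(config, artifact):
    if "neighborhoods" in config.inputs:
        nbs = synteny.read_neighborhood_tsv(config.inputs["neighborhoods"])
    else:
        sim, truth = simulate.simulate_neighborhoods(
            simulate.NeighborhoodScenario(seed=config.seed),
            loss_prob_copy2=0.5,
        )
        nbs = {
            key: synteny.GeneNeighborhood(
                species="sim", focal_gene=key, flanks=window
            )
            for key, window in sim.items()
        }
    keys = list(nbs)
    rows = []
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            sc = synteny.synteny_score(nbs[k1], nbs[k2])
            rows.append(
                {
                    "n1": k1, "n2": k2, "shared": sc.shared_count,
                    "run_up": sc.conserved_run_up,
                    "run_down": sc.conserved_run_down,
                }
            )
    pd.DataFrame(rows).to_csv(artifact("synteny_scores.tsv"), sep="\t", index=False)


def _stage_expression(config, artifact):
    if {"counts", "lengths", "paralog_map"} <= set(config.inputs):
        counts = pd.read_csv(config.inputs["counts"], sep="\t")
        lengths = pd.read_csv(config.inputs["lengths"], sep="\t")
        pmap = pd.read_csv(config.inputs["paralog_map"], sep="\t")
    else:
        counts, lengths, pmap, _ = simulate.simulate_expression(
            simulate.ExpressionScenario(seed=config.seed)
        )
    table = expr_mod.expression_table(counts, lengths)
    table.to_csv(artifact("expression_table.tsv"), sep="\t", index=False)
    heat = expr_mod.median_heatmap(table, pmap)
    heat.to_csv(artifact("median_tpm_heatmap.csv"))


def _stage_motifs(config, aln, artifact):
    msa = aln.to_protein()
    rows = []
    for taxon, seq in msa.items():
        plain = seq.replace("-", "")
        for hit in motifs_mod.scan_lxxlap(plain, taxon):
            rows.append(
                {"sequence": taxon, "motif": hit.motif, "start": hit.start,
                 "matched": hit.matched, "substitution": ""}
            )
        c = motifs_mod.scan_cterm_asn_motif(plain, taxon)
        if c is not None:
            rows.append(
                {"sequence": taxon, "motif": c.motif, "start": c.start,
                 "matched": c.matched, "substitution": c.substitution or ""}
            )
    pd.DataFrame(rows).to_csv(artifact("motif_hits.tsv"), sep="\t", index=False)
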