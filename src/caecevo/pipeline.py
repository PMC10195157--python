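"""End-to-end orchestration of the four analyses from one config.

Every stage writes TSV outputs plus a JSON-lines audit log recording the
record counts entering and leaving each filter, and a provenance block
(config hash, seed, package version) sufficient to reproduce outputs
byte-identically.  Thread count never changes results; all randomness
flows from the run seed through the component-splitting rule in
:mod:`caecevo.simulate`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence


import pandas as pd
import yaml

import caecevo
from caecevo import famdyn, simulate
from caecevo.codon import BranchPartition, CodonAlignment
from caecevo.enhancer import AnnotatedGenome, scan_species_panel
from caecevo.phylostrat import (
    CladeSpec,
    analysis_set,
    classify_orthogroups,
    read_genecount_tsv,
    summarize_partition,
)
from caecevo.selection import (
    call_selection,
    concordance_and_size_filter,
    select_alignment,
    branch_site_test,
)
from caecevo.seqio import read_fasta, write_fasta
from caecevo.trees import parse_newick

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "bonferroni",
    "run_simulate",
    "run_phylostrat",
    "run_famdyn",
    "run_selection",
    "run_enhancer",
    "run_all",
]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "clades": {
        "caecilians": list(simulate.CAECILIANS),
        "frogs": list(simulate.FROGS),
        "fish": list(simulate.FISH),
        "amniotes": list(simulate.AMNIOTES),
    },
    "simulate": {
        "n_presence": {
            "caecilian_present": 40,
            "caecilian_gain": 10,
            "loss_all_amphibia": 6,
            "loss_caecilian_only": 6,
            "loss_caecilian_amphibia_amniota_present": 4,
            "set_aside": 8,
        },
        "n_count_families": 300,
        "lambda": 0.002,
        "root_prior_mean": 2.0,
        "selection_families": {"null": 3, "positive": 1, "discordant": 1},
        "n_codons": 200,
        "enhancer": {
            "intact": ["Hom_sap", "Gal_gal"],
            "mutated": {"Xen_tro": 0.15},
            "deleted": ["Geo_ser"],
        },
    },
    "thresholds": {
        "alignment_selection": 0.05,
        "min_taxa": 7,
        "alpha": 0.05,
        "min_score": 30,
        "min_species_present": 4,
    },
    "famdyn": {"pvalue_reps": 200},
}


def _merge(base: dict, extra: Mapping) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[str] = None, overrides: Optional[Mapping] = None) -> dict:
    config = dict(DEFAULT_CONFIG)
    if path:
        with open(path) as fh:
            config = _merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _merge(config, overrides)
    return config


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _clades(config) -> CladeSpec:
    g = config["clades"]
    return CladeSpec(
        caecilians=g["caecilians"],
        frogs=g["frogs"],
        fish=g["fish"],
        amniotes=g["amniotes"],
        salamanders=g.get("salamanders", ()),
    )


def _audit(outdir: Path, stage: str, record: Mapping) -> None:
    with open(outdir / "audit.jsonl", "a") as fh:
        fh.write(json.dumps({"stage": stage, **record}, sort_keys=True) + "\n")


def _provenance(outdir: Path, config: Mapping) -> None:
    block = {
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "package_version": caecevo.__version__,
        "effective_config": config,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(block, fh, indent=2, sort_keys=True, default=str)


def bonferroni(p: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: min(1, p * m) per element."""
    if m < 1:
        raise ValueError("m must be >= 1")
    out = []
    for x in p:
        if not 0 <= x <= 1:
            raise ValueError(f"p-value out of range: {x}")
        out.append(min(1.0, x * m))
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_simulate(config: Mapping, outdir) -> Path:
    """Generate every input the downstream stages consume."""
    outdir = Path(outdir)
    sim = outdir / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    sc = config["simulate"]
    clades = _clades(config)

    species_tree = simulate.default_species_tree()
    (sim / "species_tree.nwk").write_text(species_tree.to_newick() + "\n")
    codon_tree = simulate.default_codon_tree()
    (sim / "codon_tree.nwk").write_text(codon_tree.to_newick() + "\n")

    # phylostrat inputs
    table, truth = simulate.simulate_orthogroup_presence(sc["n_presence"], clades, seed=seed)
    table.to_csv(sim / "presence.tsv", sep="\t")
    truth.to_csv(sim / "presence_truth.tsv", sep="\t")

    # famdyn inputs
    counts = simulate.simulate_counts(
        species_tree,
        lambda_=sc["lambda"],
        root_prior_mean=sc["root_prior_mean"],
        n_families=sc["n_count_families"],
        seed=seed,
    )
    counts.to_csv(sim / "genecounts.tsv", sep="\t")

    # selection inputs: per-family alignments, candidate ensembles, gene trees
    seldir = sim / "selection"
    seldir.mkdir(exist_ok=True)
    fams = sc["selection_families"]
    partition = simulate.default_foreground(codon_tree)
    pi = simulate.uniform_frequencies()
    truth_rows = []
    idx = 0
    rng = simulate.component_rng(seed, "selection")
    kinds = (
        ["null"] * fams.get("null", 0)
        + ["positive"] * fams.get("positive", 0)
        + ["discordant"] * fams.get("discordant", 0)
    )
    for kind in kinds:
        og = f"SEL{idx:04d}"
        idx += 1
        if kind == "positive":
            model = simulate.SiteClassModel(
                "ModelA", 2.5, pi, 0.425, p1=0.425, omega2=5.0
            )
            aln = simulate.simulate_codon_alignment(
                codon_tree, model, partition, n_codons=sc["n_codons"], rng=rng
            )
        else:
            model = simulate.SiteClassModel("M1Neutral", 2.5, pi, 0.5)
            aln = simulate.simulate_codon_alignment(
                codon_tree, model, None, n_codons=sc["n_codons"], rng=rng
            )
        seqs = aln.to_nucleotide()
        # realise a gapped "true" alignment by masking a codon block in one row
        sids = sorted(seqs)
        victim = sids[int(rng.integers(len(sids)))]
        start = int(rng.integers(max(1, sc["n_codons"] - 12)))
        s = seqs[victim]
        seqs[victim] = s[: 3 * start] + "-" * 9 + s[3 * (start + 3):]
        decoy = simulate.perturb_alignment(seqs, 0.2, seed=seed + idx)
        fdir = seldir / og
        fdir.mkdir(exist_ok=True)
        write_fasta({f"{sp}_g1": seq for sp, seq in seqs.items()}, fdir / "aln_cand1.fasta")
        write_fasta({f"{sp}_g1": seq for sp, seq in decoy.items()}, fdir / "aln_cand2.fasta")
        if kind == "discordant":
            gtree = simulate._random_nni(codon_tree, rng)
        else:
            gtree = parse_newick(codon_tree.to_newick())
        for leaf in gtree.dtree.leaf_node_iter():
            leaf.taxon.label = f"{leaf.taxon.label}_g1"
        (fdir / "genetree.nwk").write_text(gtree.to_newick() + "\n")
        with open(fdir / "genemap.tsv", "w") as fh:
            fh.write("gene\tspecies\n")
            for sp in sids:
                fh.write(f"{sp}_g1\t{sp}\n")
        truth_rows.append({"orthogroup": og, "kind": kind})
    pd.DataFrame(truth_rows).set_index("orthogroup").to_csv(
        seldir / "truth.tsv", sep="\t"
    )

    # enhancer inputs
    enh = sc["enhancer"]
    specs = {}
    for sp in enh.get("intact", []):
        specs[sp] = simulate.EnhancerSpeciesSpec()
    for sp, rate in enh.get("mutated", {}).items():
        specs[sp] = simulate.EnhancerSpeciesSpec(mutation_rate=float(rate))
    for sp in enh.get("deleted", []):
        specs[sp] = simulate.EnhancerSpeciesSpec(deleted=True)
    panel, etruth, queries = simulate.simulate_enhancer_panel(specs, seed=seed)
    edir = sim / "enhancer"
    edir.mkdir(exist_ok=True)
    for sp, genome in panel.items():
        write_fasta(genome.contigs, edir / f"{sp}.fasta")
        gff_lines = ["##gff-version 3"]
        for feat in genome.db.all_features():
            gff_lines.append(str(feat))
        (edir / f"{sp}.gff3").write_text("\n".join(gff_lines) + "\n")
    write_fasta(queries, edir / "queries.fasta")
    etruth.to_csv(edir / "truth.tsv", sep="\t")

    _audit(outdir, "simulate", {"n_presence": len(table), "n_counts": len(counts),
                                "n_selection_families": idx, "n_enhancer_species": len(panel)})
    return sim


def run_phylostrat(config: Mapping, outdir) -> pd.Series:
    outdir = Path(outdir)
    stage = outdir / "phylostrat"
    stage.mkdir(parents=True, exist_ok=True)
    table = read_genecount_tsv(outdir / "sim" / "presence.tsv")
    clades = _clades(config)
    partition = classify_orthogroups(table, clades)
    partition.to_csv(stage / "classes.tsv", sep="\t")
    summary = summarize_partition(partition)
    summary.to_csv(stage / "summary.tsv", sep="\t")
    kept = analysis_set(partition)
    _audit(outdir, "phylostrat", {
        "n_in": len(table),
        "n_analysis_set": len(kept),
        "n_set_aside": int(summary["set_aside"]),
    })
    return partition


def run_famdyn(config: Mapping, outdir):
    outdir = Path(outdir)
    stage = outdir / "famdyn"
    stage.mkdir(parents=True, exist_ok=True)
    counts = read_genecount_tsv(outdir / "sim" / "genecounts.tsv")
    tree = parse_newick((outdir / "sim" / "species_tree.nwk").read_text())
    clades = _clades(config)
    nonzero = counts.loc[counts.sum(axis=1) > 0]
    model = famdyn.BirthDeathFamilyModel(nonzero, tree)
    results = model.fit()
    pd.Series(
        {
            "lambda": results.lambda_,
            "root_prior_mean": results.root_prior_mean,
            "loglik": results.llf,
        }
    ).to_csv(stage / "model.tsv", sep="\t", header=False)
    reps = int(config["famdyn"]["pvalue_reps"])
    pvals = results.family_pvalues(reps=reps, seed=int(config["seed"]))
    excl = results.exclusion(
        clades, min_species_present=int(config["thresholds"]["min_species_present"])
    )
    fam_table = pd.DataFrame({"pvalue": pvals, "exclusion": excl})
    fam_table.to_csv(stage / "families.tsv", sep="\t")
    results.node_change_summary().to_csv(stage / "node_changes.tsv", sep="\t")
    _audit(outdir, "famdyn", {
        "n_in": len(counts),
        "n_fitted": len(nonzero),
        "n_analyzed": int((excl == "analyzed").sum()),
        "n_no_net_change": int((excl == "no_net_change").sum()),
        "n_insufficient_sampling": int((excl == "insufficient_sampling").sum()),
        "lambda": results.lambda_,
    })
    return results, fam_table


def run_selection(config: Mapping, outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    stage = outdir / "selection"
    stage.mkdir(parents=True, exist_ok=True)
    seldir = outdir / "sim" / "selection"
    species_tree = parse_newick((outdir / "sim" / "codon_tree.nwk").read_text())
    thresholds = config["thresholds"]
    rows, funnel = [], {"families_in": 0, "concordance_pass": 0, "tested": 0}
    results = []
    for fdir in sorted(p for p in seldir.iterdir() if p.is_dir()):
        og = fdir.name
        funnel["families_in"] += 1
        genemap = pd.read_csv(fdir / "genemap.tsv", sep="\t", index_col=0)["species"].to_dict()
        cands = [read_fasta(fdir / "aln_cand1.fasta"), read_fasta(fdir / "aln_cand2.fasta")]
        chosen_i, record = select_alignment(
            cands, threshold=float(thresholds["alignment_selection"])
        )
        gene_tree = parse_newick((fdir / "genetree.nwk").read_text())
        passed, reason = concordance_and_size_filter(
            genemap, gene_tree, species_tree, min_taxa=int(thresholds["min_taxa"])
        )
        rows.append(
            {"orthogroup": og, "alignment": f"cand{chosen_i + 1}",
             "alignment_reason": record["reason"], "filter": reason}
        )
        if not passed:
            continue
        funnel["concordance_pass"] += 1
        chosen = {genemap[g]: s for g, s in cands[chosen_i].items()}
        aln = CodonAlignment.from_nucleotide(chosen)
        sub_tree = species_tree.restrict(set(chosen))
        partition = BranchPartition.from_clade(
            sub_tree,
            set(config["clades"]["caecilians"]) & set(chosen),
            mode="stem+clade",
        )
        res = branch_site_test(
            aln, sub_tree, partition, orthogroup=og, lineage="caecilian"
        )
        results.append(res)
        funnel["tested"] += 1
    called = call_selection(results, alpha=float(thresholds["alpha"]))
    out = pd.DataFrame(
        [
            {
                "orthogroup": r.orthogroup,
                "lineage": r.lineage,
                "lnl_m1": r.lnl_m1,
                "lnl_null": r.lnl_null,
                "lnl_alt": r.lnl_alt,
                "p_vs_m1": r.p_vs_m1,
                "p_vs_null": r.p_vs_null,
                "omega2": r.omega2,
                "p_adjusted": r.p_adjusted,
                "selected": r.selected,
            }
            for r in called
        ]
    )
    if not out.empty:
        out = out.set_index("orthogroup")
    out.to_csv(stage / "results.tsv", sep="\t")
    pd.DataFrame(rows).set_index("orthogroup").to_csv(stage / "filter_audit.tsv", sep="\t")
    funnel["called"] = int(out["selected"].sum()) if not out.empty else 0
    _audit(outdir, "selection", funnel)
    return out


def run_enhancer(config: Mapping, outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    stage = outdir / "enhancer"
    stage.mkdir(parents=True, exist_ok=True)
    edir = outdir / "sim" / "enhancer"
    queries = read_fasta(edir / "queries.fasta")
    panel = {}
    for fasta in sorted(edir.glob("*.fasta")):
        sp = fasta.stem
        if sp == "queries":
            continue
        contigs = read_fasta(fasta)
        gff_text = (edir / f"{sp}.gff3").read_text()
        panel[sp] = AnnotatedGenome(contigs, gff_text)
    min_score = float(config["thresholds"]["min_score"])
    recipe = {sp: {"kind": "intron", "gene": "LMBR1", "exons": (5, 6)} for sp in panel}
    records = scan_species_panel(
        queries["zrs"], panel, region_id="zrs", recipe=recipe, min_score=min_score
    )
    recipe_ctrl = {sp: {"kind": "intergenic", "genes": ("DLX1", "DLX2")} for sp in panel}
    records += scan_species_panel(
        queries["i12a"], panel, region_id="i12a", recipe=recipe_ctrl, min_score=min_score
    )
    out = pd.DataFrame(
        [
            {
                "species": r.species,
                "region": r.region_id,
                "fraction": r.fraction,
                "motif_present": r.motif_present,
                "n_hits": len(r.hits),
                "genome_wide_fallback": r.used_genome_wide,
                "status": r.status,
            }
            for r in records
        ]
    ).set_index(["species", "region"])
    out.to_csv(stage / "conservation.tsv", sep="\t")
    _audit(outdir, "enhancer", {"n_records": len(out)})
    return out


def run_all(config: Mapping, outdir) -> dict:
    """Simulate inputs then run all four analyses; returns stage outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _provenance(outdir, dict(config))
    run_simulate(config, outdir)
    partition = run_phylostrat(config, outdir)
    fam_results, fam_table = run_famdyn(config, outdir)
    sel = run_selection(config, outdir)
    enh = run_enhancer(config, outdir)
    return {
        "phylostrat": partition,
        "famdyn": (fam_results, fam_table),
        "selection": sel,
        "enhancer": enh,
    }
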