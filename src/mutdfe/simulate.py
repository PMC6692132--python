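"""Synthetic-data generator for the full pipeline.

Emulates the statistical structure of the study's inputs: a bacterial CDS
with a list of classified single-nucleotide substitutions, replicate
competition colony counts with binomial plate-sampling noise, a mixture DFE
whose beneficial component is an exact generalised-Pareto tail, a linear
expression-fitness relation with Gaussian noise, and a polytomous phylogeny
whose per-site binary tip states become more probable with fitness.

Everything is keyed off :class:`mutdfe.config.SimConfig`; identical configs
(including the seed) give byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .config import SimConfig
from .mutations import (BACTERIAL_TABLE, CodingSequence, MutationClass,
                        PointMutation, classify_mutation)

__all__ = [
    "simulate_gene",
    "simulate_mutation_set",
    "simulate_true_dfe",
    "simulate_competitions",
    "simulate_expression",
    "simulate_tree_and_states",
    "simulate_reference_set",
    "simulate_trna_table",
    "write_dataset",
    "MARKER_CONTROL_ID",
]

MARKER_CONTROL_ID = "marker-control"

_SENSE = sorted(set(BACTERIAL_TABLE.forward_table) - {"ATG"})
_STOPS = tuple(sorted(BACTERIAL_TABLE.stop_codons))
_BASES = np.array(list("ACGT"))


def simulate_gene(config: SimConfig, flank: int = 100) -> CodingSequence:
    """Random CDS of ``gene_length_codons`` sense codons plus a stop, with flanks."""
    rng = config.rng("gene")
    body = [_SENSE[i] for i in rng.integers(0, len(_SENSE),
                                            size=config.gene_length_codons - 1)]
    seq = "ATG" + "".join(body) + _STOPS[rng.integers(0, len(_STOPS))]
    f5 = "".join(rng.choice(_BASES, size=flank))
    f3 = "".join(rng.choice(_BASES, size=flank))
    return CodingSequence(id="synthetic-gene", seq=seq, flank5=f5, flank3=f3)


def simulate_mutation_set(cds: CodingSequence, config: SimConfig) -> pd.DataFrame:
    """Sample substitutions with the configured class composition.

    All possible single-nucleotide substitutions in sense codons are
    enumerated and classified; ``n_syn``/``n_nonsyn``/``n_nonsense`` are
    drawn without replacement from each class.
    """
    rng = config.rng("mutations")
    pools: dict[str, list[PointMutation]] = {c: [] for c in MutationClass.ALL}
    for pos in range(1, len(cds.seq) - 2):       # skip the terminal stop codon
        ref = cds.seq[pos - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            mut = PointMutation(cds_position=pos, ref_base=ref, alt_base=alt)
            pools[classify_mutation(cds, mut)].append(mut)
    want = {"synonymous": config.n_syn, "nonsynonymous": config.n_nonsyn,
            "nonsense": config.n_nonsense}
    rows = []
    for mclass in MutationClass.ALL:
        pool, k = pools[mclass], want[mclass]
        if k > len(pool):
            raise ValueError(f"gene too short: only {len(pool)} possible "
                             f"{mclass} substitutions, {k} requested")
        for i in sorted(rng.choice(len(pool), size=k, replace=False)):
            m = pool[i]
            rows.append({"cds_position": m.cds_position, "ref_base": m.ref_base,
                         "alt_base": m.alt_base, "class": mclass,
                         "site_label": m.site_label,
                         "protein_label": m.protein_label(cds)})
    df = pd.DataFrame(rows).sort_values(["cds_position", "alt_base"]).reset_index(drop=True)
    df.insert(0, "mutation_id", [f"m{i + 1:03d}" for i in range(len(df))])
    return df


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_true_dfe(config: SimConfig,
                      mutations: pd.DataFrame | None = None) -> pd.DataFrame:
    """True relative fitness per mutation from the configured mixture.

    Synonymous/nonsynonymous effects: beneficial with probability
    ``p_beneficial`` (s an exact GPD(tau, kappa) draw), otherwise a
    non-positive near-neutral or deleterious Gaussian draw truncated to
    (-1, 0].  Nonsense effects come from the deleterious component shifted
    by ``nonsense_shift`` — strongly deleterious, never beneficial.
    """
    config.validate()
    mix = config.dfe_mixture
    if mix.tail_kappa < -1:
        raise ValueError("tail_kappa < -1 puts the GPD outside the usable "
                         "(finite-density) regime")
    rng = config.rng("dfe")
    if mutations is None:
        classes = ([MutationClass.SYNONYMOUS] * config.n_syn
                   + [MutationClass.NONSYNONYMOUS] * config.n_nonsyn
                   + [MutationClass.NONSENSE] * config.n_nonsense)
        ids = [f"m{i + 1:03d}" for i in range(len(classes))]
    else:
        classes = list(mutations["class"].astype(str))
        ids = list(mutations["mutation_id"].astype(str))

    s = np.empty(len(classes))
    for i, mclass in enumerate(classes):
        if mclass == MutationClass.NONSENSE:
            s[i] = _truncated_normal(rng, mix.deleterious_mean + mix.nonsense_shift,
                                     mix.deleterious_sd, -1 + 1e-9, 0.0, 1)[0]
        elif rng.random() < mix.p_beneficial:
            # genpareto(c=kappa, scale=tau); kappa=-1 is Uniform(0, tau)
            u = rng.random()
            if abs(mix.tail_kappa) < 1e-12:
                s[i] = -mix.tail_tau * np.log1p(-u)
            else:
                s[i] = mix.tail_tau / mix.tail_kappa * ((1 - u) ** -mix.tail_kappa - 1)
        elif rng.random() < mix.p_deleterious:
            s[i] = _truncated_normal(rng, mix.deleterious_mean, mix.deleterious_sd,
                                     -1 + 1e-9, 0.0, 1)[0]
        else:
            s[i] = -abs(rng.normal(0.0, mix.neutral_sd)) if mix.neutral_sd > 0 else 0.0
    return pd.DataFrame({"mutation_id": ids, "class": classes, "true_w": 1.0 + s})


def simulate_competitions(true_dfe: pd.DataFrame, config: SimConfig,
                          include_marker_control: bool = True) -> pd.DataFrame:
    """Replicate colony-count table by binomial plate sampling.

    Each replicate plates ``colonies_sampled`` colonies initially (mutant
    frequency ~ 0.5 from the 1:1 mix) and finally, where the final mutant
    frequency is the deterministic growth outcome
    ``f0 w^d / (f0 w^d + (1 - f0))`` of the plated initial frequency f0.
    Counts of mutant and reference sum to ``colonies_sampled`` per plate.
    A neutral marker-control competition (true w = 1) is appended under
    ``mutation_id = "marker-control"`` unless disabled.
    """
    if np.any(true_dfe["true_w"].to_numpy() <= 0):
        raise ValueError("true_w must be positive")
    rng = config.rng("competitions")
    N = config.assay.colonies_sampled
    d = config.assay.doublings
    rows = []
    items = list(zip(true_dfe["mutation_id"].astype(str), true_dfe["true_w"]))
    if include_marker_control:
        items.append((MARKER_CONTROL_ID, 1.0))
    for mid, w in items:
        for rep in range(1, config.assay.n_replicates + 1):
            mi = int(rng.binomial(N, 0.5))
            mi = min(max(mi, 1), N - 1)     # keep both strains on the plate
            f0 = mi / N
            grown = f0 * w ** d
            f1 = grown / (grown + (1 - f0))
            mf = int(rng.binomial(N, f1))
            rows.append({"mutation_id": mid, "replicate": rep,
                         "mutant_initial": mi, "ref_initial": N - mi,
                         "mutant_final": mf, "ref_final": N - mf,
                         "doublings": d})
    return pd.DataFrame(rows)


def simulate_expression(true_dfe: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Relative transcript level linearly linked to true fitness."""
    rng = config.rng("expression")
    e = config.expression
    w = true_dfe["true_w"].to_numpy(dtype=float)
    noise = rng.normal(0.0, e.noise_sd, size=w.size) if e.noise_sd > 0 else 0.0
    return pd.DataFrame({"mutation_id": true_dfe["mutation_id"].astype(str),
                         "relative_expression": e.intercept + e.slope * w + noise})


def _random_bifurcating(labels: list[str], rng: np.random.Generator) -> dendropy.Tree:
    """Random rooted bifurcating topology by sequential random joins."""
    ns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = ns.get_taxon(lab)
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def _collapse_to_polytomies(tree: dendropy.Tree, k: int,
                            rng: np.random.Generator) -> int:
    """Collapse ``k`` disjoint internal edges, creating ``k`` polytomies."""
    edges = [nd for nd in tree.preorder_internal_node_iter()
             if nd.parent_node is not None]
    rng.shuffle(edges)
    used: set[int] = set()
    done = 0
    for nd in edges:
        if done >= k:
            break
        if id(nd) in used or id(nd.parent_node) in used:
            continue
        parent = nd.parent_node
        for child in nd.child_nodes():
            nd.remove_child(child)
            parent.add_child(child)
        parent.remove_child(nd)
        used.update((id(nd), id(parent)))
        done += 1
    return done


def simulate_tree_and_states(config: SimConfig, true_dfe: pd.DataFrame):
    """Random polytomous phylogeny plus fitness-linked binary tip states.

    Returns ``(newick_string, tip_states_frame)``.  A mutation is present on
    at least one tip with probability
    ``logistic(intercept + slope * log w)``; carriers are scattered
    uniformly (1 + Binomial extra tips), so scattered patterns imply
    multiple parsimony origins.
    """
    tc = config.tree
    rng = config.rng("tree")
    labels = [f"t{i + 1:02d}" for i in range(tc.n_tips)]
    tree = _random_bifurcating(labels, rng)
    n_internal = sum(1 for _ in tree.preorder_internal_node_iter())
    k = int(round(tc.polytomy_fraction * n_internal))
    _collapse_to_polytomies(tree, k, rng)
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()

    srng = config.rng("states")
    rows = []
    for mid, w in zip(true_dfe["mutation_id"].astype(str), true_dfe["true_w"]):
        p = expit(tc.presence_logit_intercept + tc.presence_logit_slope * np.log(w))
        carriers: set[str] = set()
        if srng.random() < p:
            extra = srng.binomial(tc.n_tips - 1, tc.carrier_extra_p)
            idx = srng.choice(tc.n_tips, size=1 + extra, replace=False)
            carriers = {labels[int(i)] for i in idx}
        for lab in labels:
            rows.append({"site": mid, "tip": lab,
                         "state": int(lab in carriers)})
    return newick, pd.DataFrame(rows)


def simulate_reference_set(config: SimConfig, n_genes: int = 20,
                           n_codons: int = 200, bias: float = 8.0) -> list[str]:
    """Codon-biased reference CDSs emulating a highly expressed gene set.

    Within each synonymous family one codon (chosen per run) is preferred
    with relative odds ``bias``; the resulting usage table has informative,
    non-uniform weights.
    """
    rng = config.rng("reference")
    families: dict[str, list[str]] = {}
    for codon, aa in BACTERIAL_TABLE.forward_table.items():
        families.setdefault(aa, []).append(codon)
    preferred = {aa: cods[rng.integers(0, len(cods))]
                 for aa, cods in families.items()}
    aas = list(families)
    genes = []
    for _ in range(n_genes):
        codons = []
        for aa in rng.choice(aas, size=n_codons):
            cods = families[aa]
            p = np.array([bias if c == preferred[aa] else 1.0 for c in cods])
            codons.append(cods[rng.choice(len(cods), p=p / p.sum())])
        genes.append("".join(codons))
    return genes


def simulate_trna_table(config: SimConfig) -> pd.DataFrame:
    """Plausible anticodon copy-number table covering every sense codon.

    Roughly half of all possible anticodons carry Poisson-distributed copy
    numbers; any codon left undecodable after wobble rules gets one copy of
    its Watson-Crick anticodon, mimicking the minimal decoding sets of real
    genomes.
    """
    from .mutations import TRNACopyTable, _revcomp

    rng = config.rng("trna")
    anticodons = sorted({_revcomp(c) for c in BACTERIAL_TABLE.forward_table})
    copies = {a: int(rng.poisson(2.0)) for a in anticodons
              if rng.random() < 0.55}
    copies = {a: n for a, n in copies.items() if n > 0}
    for _ in range(200):
        table = TRNACopyTable(copies)
        W = table.absolute_adaptiveness()
        undecoded = [c for c, w in W.items() if w == 0]
        if not undecoded:
            break
        wc = _revcomp(undecoded[0])
        if undecoded[0] == "ATA":
            wc = "CAT"      # lysidine pathway
        copies[wc] = copies.get(wc, 0) + 1
    return pd.DataFrame(sorted(copies.items()), columns=["anticodon", "copies"])


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_dataset(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate and write the complete synthetic input bundle.

    Files: ``gene.fasta`` (CDS plus flanks, with the CDS span in the
    header), ``mutations.csv``, ``competitions.csv``, ``expression.csv``,
    ``tree.nwk``, ``tip_states.csv``, ``cai_reference.fasta``,
    ``trna_copies.csv`` and ``truth.json`` (all true parameters and true
    per-mutation fitness).  Deterministic given the config.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cds = simulate_gene(config)
    mutations = simulate_mutation_set(cds, config)
    true_dfe = simulate_true_dfe(config, mutations)
    competitions = simulate_competitions(true_dfe, config)
    expression = simulate_expression(true_dfe, config)
    newick, tip_states = simulate_tree_and_states(config, true_dfe)
    reference = simulate_reference_set(config)
    trna = simulate_trna_table(config)

    paths: dict[str, Path] = {}

    def _csv(name: str, df: pd.DataFrame) -> None:
        p = outdir / name
        df.to_csv(p, index=False, lineterminator="\n")
        paths[name] = p

    p = outdir / "gene.fasta"
    full = cds.flank5 + cds.seq + cds.flank3
    header = (f">{cds.id} cds_start={len(cds.flank5) + 1} "
              f"cds_end={len(cds.flank5) + len(cds.seq)}")
    p.write_text(header + "\n" + "\n".join(
        full[i:i + 70] for i in range(0, len(full), 70)) + "\n")
    paths["gene.fasta"] = p

    _csv("mutations.csv", mutations)
    _csv("competitions.csv", competitions)
    _csv("expression.csv", expression)
    _csv("tip_states.csv", tip_states)

    p = outdir / "tree.nwk"
    p.write_text(newick + "\n")
    paths["tree.nwk"] = p

    p = outdir / "cai_reference.fasta"
    p.write_text("".join(f">ref{i + 1:02d}\n{g}\n" for i, g in enumerate(reference)))
    paths["cai_reference.fasta"] = p

    _csv("trna_copies.csv", trna)

    p = outdir / "truth.json"
    truth = {"config": config.to_dict(),
             "true_w": dict(zip(true_dfe["mutation_id"],
                                true_dfe["true_w"].round(12)))}
    p.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    paths["truth.json"] = p
    return paths
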