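"""Orchestration of the full codon-usage analysis.

``run_full_analysis`` composes the stages in order -- counting, per-set
profiles and Nc, modal usages, correspondence analysis with centroids,
adaptiveness/tAI (with optional Sij training), bias tests and the group call,
HEP/LEP conserved/variable domains when abundance data and alignments are
available, and usage-distance neighbor-joining trees -- writing every
artifact plus a manifest with content hashes.  ``selection_ratio_study``
builds the natural-versus-null distance contrast on synthetic families.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .bias import c_bias_test, classify_group, delta_cuf, u_bias_test
from .ca import ca_fit, ca_project, set_centroids
from .code import GeneticCode, default_code
from .core import (CodingSequence, CodonCountTable, GeneSetPartition,
                   UsageProfile, count_codons, cuf_profile,
                   effective_number_of_codons, gc3_of_counts, rscu_profile)
from .disttree import DistanceMatrix, distance_matrix, nj_tree, selection_ratio
from .domains import (AbundanceTable, backthread, classify_columns,
                      extract_domains, select_hep_lep)
from .modal import ModalResult, modal_sequence, modal_usage
from .simulate import (GenomeSimConfig, balanced_tree, evolve_m0, f3x4,
                       generate_ortholog_family, M0Params)
from .tai import (SijWeights, TRNAPool, absolute_adaptiveness, genome_tai,
                  modal_tai, train_sij)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and parameters of a full analysis run."""

    cds_fasta: str
    partition_tsv: str
    out_dir: str
    trna_tsv: str | None = None
    abundance_tsv: str | None = None
    alignments_dir: str | None = None
    seed: int = 0
    p_cutoff: float = 0.1
    hep_q: float = 0.9
    lep_q: float = 0.1
    group_margin: float = 0.03
    train_restarts: int = 5
    train_sij_weights: bool = True
    modal_min_codons: int = 10020

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for attr in ("cds_fasta", "partition_tsv"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise ValueError(f"{attr} path does not exist: {p}")
        for attr in ("trna_tsv", "abundance_tsv", "alignments_dir"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{attr} path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _ancestry_sets(partition: GeneSetPartition) -> dict[str, list[str]]:
    """Split set names into singletons / ordered cores / PHE by convention."""
    names = list(partition.sets)
    cores = sorted((n for n in names if n.upper().startswith("C")
                    and n[1:].isdigit()), key=lambda n: int(n[1:]))
    singles = [n for n in names if n.lower().startswith("single")]
    phe = [n for n in names if n.upper() == "PHE"]
    return {"singletons": singles, "cores": cores, "phe": phe}


def run_full_analysis(cfg: RunConfig,
                      code: GeneticCode | None = None) -> dict:
    """Run every stage the inputs allow; return the manifest dictionary.

    Stages that need missing optional inputs are skipped with a notice in the
    manifest; a failing stage raises :class:`StageError` naming it.  Rerun
    with the same config and seed, the artifact bytes are identical.
    """
    code = code or default_code()
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "parameters": {
        "p_cutoff": cfg.p_cutoff, "hep_q": cfg.hep_q, "lep_q": cfg.lep_q,
        "group_margin": cfg.group_margin,
        "modal_min_codons": cfg.modal_min_codons,
        "train_restarts": cfg.train_restarts},
        "stages": {}, "artifacts": {}, "notices": []}

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["artifacts"][name] = _sha256(path)
        return path

    stage = "load"
    try:
        seqs = cio.read_cds_fasta(cfg.cds_fasta)
        partition = cio.read_partition_tsv(cfg.partition_tsv)
        pool = cio.read_trna_tsv(cfg.trna_tsv) if cfg.trna_tsv else None
        abund = (cio.read_abundance_tsv(cfg.abundance_tsv)
                 if cfg.abundance_tsv else None)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    try:
        stage = "count"
        table = count_codons(seqs, code)
        emit("counts.tsv", lambda p: cio.write_count_table(table, p))
        manifest["stages"][stage] = "ok"

        stage = "profiles"
        set_rows = []
        profiles: dict[str, UsageProfile] = {}
        for name, members in partition.sets.items():
            present = [g for g in members if g in table.genes]
            if not present:
                manifest["notices"].append(f"set {name} has no genes; skipped")
                continue
            pooled = table.aggregate(present)
            prof = rscu_profile(pooled, code, label=name)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prof.nc = effective_number_of_codons(pooled, code)
            profiles[name] = prof
            emit(f"profile_{name}.tsv",
                 lambda p, pr=prof: cio.write_profile_tsv(pr, p, code))
            set_rows.append({"set": name, "n_genes": len(present),
                             "gc3": prof.gc3, "nc": prof.nc})
        pd.DataFrame(set_rows).to_csv(out / "sets_summary.tsv", sep="\t",
                                      index=False, float_format="%.10g")
        manifest["artifacts"]["sets_summary.tsv"] = _sha256(out / "sets_summary.tsv")
        manifest["stages"][stage] = "ok"

        stage = "modal"
        modal_profiles: dict[str, UsageProfile] = {}
        modal_seqs: list[CodingSequence] = []
        for name, members in partition.sets.items():
            present = [g for g in members if g in table.genes]
            if len(present) < 2:
                manifest["notices"].append(
                    f"set {name}: fewer than 2 genes; modal skipped")
                continue
            result = modal_usage(table.subset(present), code,
                                 p_cutoff=cfg.p_cutoff)
            result.profile.label = name
            modal_profiles[name] = result.profile
            seq = modal_sequence(result.profile,
                                 min_codons=cfg.modal_min_codons, code=code,
                                 seq_id=f"modal|{name}|n={cfg.modal_min_codons}")
            modal_seqs.append(seq)
            emit(f"modal_{name}.tsv",
                 lambda p, pr=result.profile: cio.write_profile_tsv(pr, p, code))
        if modal_seqs:
            emit("modal_sequences.fasta",
                 lambda p: cio.write_fasta(modal_seqs, p))
        manifest["stages"][stage] = "ok"

        stage = "ca"
        fit = ca_fit(table.counts, input_kind="RCC")
        emit("ca_row_coords.tsv",
             lambda p: fit.row_coords.to_csv(p, sep="\t", float_format="%.10g"))
        centroids = set_centroids(fit, partition)
        emit("ca_centroids.tsv",
             lambda p: centroids.to_csv(p, sep="\t", float_format="%.10g"))
        if modal_seqs:
            modal_counts = count_codons(modal_seqs, code)
            sup = ca_project(fit, modal_counts.counts)
            emit("ca_modal_projection.tsv",
                 lambda p: sup.to_csv(p, sep="\t", float_format="%.10g"))
        manifest["stages"][stage] = "ok"

        stage = "adaptiveness"
        mtai_by_set: dict[str, float] = {}
        if pool is not None:
            if cfg.train_sij_weights:
                training = train_sij(table, pool, restarts=cfg.train_restarts,
                                     seed=cfg.seed, code=code)
                weights = training.weights
                emit("sij.json", lambda p: Path(p).write_text(
                    weights.to_json(rho=training.rho, seed=training.seed)))
            else:
                weights = SijWeights({})
            adapt = absolute_adaptiveness(pool, weights, code)
            emit("adaptiveness.tsv",
                 lambda p: cio.write_adaptiveness_tsv(adapt, p))
            tai = genome_tai(table, adapt)
            emit("gene_tai.tsv", lambda p: tai.to_csv(p, sep="\t",
                                                      float_format="%.10g"))
            for name, prof in modal_profiles.items():
                mtai_by_set[name] = modal_tai(prof, adapt, code)
            emit("mtai.tsv", lambda p: pd.Series(mtai_by_set, name="mtai")
                 .rename_axis("set").to_csv(p, sep="\t", float_format="%.10g"))
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped (no tRNA table)"
            manifest["notices"].append("adaptiveness skipped: no tRNA table")

        stage = "bias"
        groups = _ancestry_sets(partition)
        bias_out: dict = {}
        if groups["cores"] and len(groups["cores"]) >= 2:
            first, last = groups["cores"][0], groups["cores"][-1]
            if first in modal_profiles and last in modal_profiles:
                bp = delta_cuf(modal_profiles[last], modal_profiles[first], code)
                ct, ut = c_bias_test(bp), u_bias_test(bp)
                bias_out["cn_vs_c1"] = {
                    "comparison": f"{last} - {first}",
                    "c_bias": {"mean_delta": ct.mean_delta, "t": ct.statistic,
                               "p": ct.p_value},
                    "u_bias": {"mean_delta": ut.mean_delta, "t": ut.statistic,
                               "p": ut.p_value}}
                emit("delta_cn_c1.tsv", lambda p: bp.delta.rename("delta")
                     .rename_axis("codon").to_csv(p, sep="\t",
                                                  float_format="%.10g"))
        if bias_out:
            emit("bias_tests.json", lambda p: Path(p).write_text(
                json.dumps(bias_out, indent=2, sort_keys=True)))
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped (no C1/Cn modal profiles)"

        stage = "classify"
        gc_total = _genomic_gc(seqs)
        call = None
        if (groups["singletons"] and groups["cores"] and groups["phe"]
                and all(n in profiles for n in
                        (groups["singletons"][0], groups["cores"][-1],
                         groups["phe"][0]))):
            call = classify_group(
                gc_total,
                {"singletons": profiles[groups["singletons"][0]].gc3,
                 "core": profiles[groups["cores"][-1]].gc3,
                 "phe": profiles[groups["phe"][0]].gc3},
                margin=cfg.group_margin)
            emit("group_call.json", lambda p: Path(p).write_text(json.dumps(
                {"group": call.group, "evidence": call.evidence}, indent=2,
                sort_keys=True)))
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped (missing gene sets)"

        stage = "domains"
        domain_profiles: dict[str, UsageProfile] = {}
        if abund is not None and cfg.alignments_dir is not None:
            domain_profiles = _domain_stage(cfg, code, table, partition,
                                            abund, out, manifest, emit)
            manifest["stages"][stage] = "ok" if domain_profiles else \
                "skipped (no usable families)"
        else:
            manifest["stages"][stage] = "skipped (no abundance/alignments)"

        stage = "disttree"
        tree_profiles = dict(modal_profiles)
        tree_profiles.update(domain_profiles)
        if len(tree_profiles) >= 3:
            dm = distance_matrix(tree_profiles, code)
            emit("usage_distances.tsv", lambda p: cio.write_distance_tsv(dm, p))
            tree = nj_tree(dm)
            emit("usage_tree.nwk", lambda p: cio.write_newick(tree.newick(), p))
            manifest["stages"][stage] = "ok"
        else:
            manifest["stages"][stage] = "skipped (fewer than 3 profiles)"
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _genomic_gc(seqs: Sequence[CodingSequence]) -> float:
    gc = total = 0
    for s in seqs:
        gc += sum(1 for b in s.seq if b in "GC")
        total += len(s.seq)
    return gc / total if total else math.nan


def _domain_stage(cfg, code, table, partition, abund, out, manifest, emit
                  ) -> dict[str, UsageProfile]:
    """HEP/LEP selection plus cr/vr extraction over an alignments directory.

    Expects per family ``<fam>.aa.fasta`` (aligned) and ``<fam>.cds.fasta``
    (unaligned CDS); the family's reference member must be a gene of this
    genome.
    """
    groups = _ancestry_sets(partition)
    if not groups["cores"]:
        manifest["notices"].append("domains: no core sets")
        return {}
    core_genes = [g for name in groups["cores"]
                  for g in partition.sets[name]]
    hep, lep = select_hep_lep(abund, core_genes, cfg.hep_q, cfg.lep_q)
    pd.DataFrame({"gene": list(hep) + list(lep),
                  "class": ["HEP"] * len(hep) + ["LEP"] * len(lep)}).to_csv(
        out / "hep_lep.tsv", sep="\t", index=False)
    manifest["artifacts"]["hep_lep.tsv"] = _sha256(out / "hep_lep.tsv")
    aln_dir = Path(cfg.alignments_dir)
    collections: dict[str, list[CodingSequence]] = {
        "HEP_cr": [], "HEP_vr": [], "LEP_cr": [], "LEP_vr": []}
    for aa_path in sorted(aln_dir.glob("*.aa.fasta")):
        fam_id = aa_path.name[:-len(".aa.fasta")]
        cds_path = aln_dir / f"{fam_id}.cds.fasta"
        if not cds_path.exists():
            manifest["notices"].append(f"domains: {fam_id} lacks CDS; skipped")
            continue
        aa_rows = cio.read_alignment_fasta(aa_path)
        cds = {s.id: s.seq for s in cio.read_cds_fasta(cds_path)}
        reference = next((m for m in aa_rows if m in set(hep) | set(lep)), None)
        if reference is None:
            continue
        side = "HEP" if reference in hep else "LEP"
        aln = backthread(aa_rows, cds, family_id=fam_id,
                         reference=reference, code=code)
        classify_columns(aln)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for which in ("cr", "vr"):
                seq = extract_domains(aln, which)
                if seq.seq:
                    collections[f"{side}_{which}"].append(seq)
    out_profiles: dict[str, UsageProfile] = {}
    domain_seqs: list[CodingSequence] = []
    for name, seq_list in collections.items():
        if len(seq_list) < 2:
            manifest["notices"].append(
                f"domains: {name} has {len(seq_list)} sequences; "
                "modal usage skipped")
            continue
        sub = count_codons(seq_list, code)
        result = modal_usage(sub, code, p_cutoff=cfg.p_cutoff)
        result.profile.label = name
        out_profiles[name] = result.profile
        domain_seqs.extend(seq_list)
    if domain_seqs:
        emit("domain_sequences.fasta",
             lambda p: cio.write_fasta(domain_seqs, p))
    return out_profiles


# ---------------------------------------------------------------------------
# natural vs simulated distance contrast
# ---------------------------------------------------------------------------

def selection_ratio_study(seed: int,
                          n_families: int = 10,
                          n_members: int = 8,
                          n_codons: int = 240,
                          tree_depth: float = 0.45,
                          code: GeneticCode | None = None) -> dict:
    """Natural-vs-null contrast of HEP/LEP conserved/variable usages.

    'Natural' ortholog families keep codon selection: HEP families draw
    codons from the selected (expression-blended) profile, LEP families from
    the mutational profile.  Each family's null counterpart evolves the same
    reference CDS under M0 with F3x4 frequencies (no codon selection), at an
    omega matching the family's planted conservation structure.  Both arms
    run through the same cr/vr extraction, modal-usage and distance pipeline;
    the headline number is the natural/simulated ratio of the HEP_cr to
    LEP_vr distance.
    """
    from .simulate import mixture_profile, study_profiles

    code = code or default_code()
    mut, sel, u = study_profiles(code)
    hep_profile = mixture_profile(mut, mixture_profile(sel, u, 0.5, code),
                                  0.9, code, label="HEP")
    lep_profile = mixture_profile(mut, sel, 0.1, code, label="LEP")
    arms = {"HEP": (hep_profile, 0.6, 0.2, 0.06),
            "LEP": (lep_profile, 0.4, 0.3, 0.25)}
    natural: dict[str, list[CodingSequence]] = {}
    simulated: dict[str, list[CodingSequence]] = {}
    rng = np.random.default_rng(seed)
    for side, (profile, fcons, fvar, omega_slow) in arms.items():
        for fam in range(n_families):
            fam_seed = int(rng.integers(0, 2 ** 31 - 1))
            aa_rows, cds = generate_ortholog_family(
                profile, n_members=n_members, n_codons=n_codons,
                frac_conserved=fcons, frac_variable=fvar,
                seed=fam_seed, family_id=f"{side}{fam}", code=code)
            aln = backthread(aa_rows, cds, family_id=f"{side}{fam}", code=code)
            classify_columns(aln)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for which in ("cr", "vr"):
                    seq = extract_domains(aln, which)
                    if seq.seq:
                        natural.setdefault(f"{side}_{which}", []).append(seq)
            # null arm: same reference CDS, M0/F3x4, no codon selection
            ref_cds = cds[aln.reference]
            omega_sites = np.where(
                np.array(aln.column_classes) == "conserved",
                omega_slow, 1.2)
            params = M0Params(kappa=2.0, omega=omega_sites,
                              pi=f3x4([ref_cds], code),
                              tree=balanced_tree(n_members, tree_depth))
            leaves = evolve_m0(CodingSequence(id="root", seq=ref_cds),
                               params, seed=fam_seed + 1, code=code)
            sim_aa = {name: code.translate(s.seq)
                      for name, s in leaves.items()}
            sim_cds = {name: s.seq for name, s in leaves.items()}
            sim_aln = backthread(sim_aa, sim_cds,
                                 family_id=f"{side}{fam}_SIM", code=code)
            classify_columns(sim_aln)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for which in ("cr", "vr"):
                    seq = extract_domains(sim_aln, which)
                    if seq.seq:
                        simulated.setdefault(f"{side}_{which}", []).append(seq)

    def modal_profiles(collections: dict[str, list[CodingSequence]]
                       ) -> dict[str, UsageProfile]:
        out: dict[str, UsageProfile] = {}
        for name, seq_list in collections.items():
            if len(seq_list) < 2:
                continue
            result = modal_usage(count_codons(seq_list, code), code,
                                 p_cutoff=0.05)
            result.profile.label = name
            out[name] = result.profile
        return out

    nat_profiles = modal_profiles(natural)
    sim_profiles = modal_profiles(simulated)
    needed = ("HEP_cr", "LEP_vr")
    for name in needed:
        if name not in nat_profiles or name not in sim_profiles:
            raise RuntimeError(f"collection {name} too sparse in one arm")
    nat_dm = distance_matrix(nat_profiles, code)
    sim_dm = distance_matrix(sim_profiles, code)
    ratio = selection_ratio(nat_dm, sim_dm, "HEP_cr", "LEP_vr")
    return {"ratio": ratio, "natural": nat_dm, "simulated": sim_dm,
            "natural_profiles": nat_profiles,
            "simulated_profiles": sim_profiles}
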