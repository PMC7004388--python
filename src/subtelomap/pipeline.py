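"""End-to-end orchestration and the truth-evaluation harness.

``run_pipeline`` drives simulate -> assemble -> call -> blocks -> popstats
over a named scenario, writing every stage's artifacts as plain text
(BNX molecules, CMAP contigs, TSV tables) so each stage can be re-run
independently from the previous stage's files.  A manifest records the
configuration, derived per-stage seeds and content digests of every
artifact; identical configurations produce identical artifacts.

``evaluate_against_truth`` compares calls with the simulation truth:
haplotype-cluster agreement (adjusted Rand index), extension error, gap
assessment confusion and block presence precision/recall.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import armcall, blocks as blocks_mod, popstats as popstats_mod
from .align import AlignmentParams
from .assemble import AssemblyResult, ConsensusMap, assemble_arm
from .core import LabelMap, PipelineParams, child_seed
from .refmaps import read_cmap, write_cmap
from .scenarios import ArmScenario, multi_arm
from .simulate import (PopulationSpec, SimulatedMolecule, default_block_library,
                       read_bnx, sample_population, simulate_diploid_arm,
                       write_bnx)

__all__ = ["RunConfig", "run_pipeline", "evaluate_against_truth",
           "adjusted_rand_index"]

_STAGES = ("simulate", "assemble", "call", "blocks", "popstats")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    n_arms: int = 2
    superpop_sizes: dict[str, int] = field(
        default_factory=lambda: {"AFR": 3, "EUR": 3})
    # frequency of the block-bearing reference haplotype per superpop
    ref_hap_frequency: dict[str, float] = field(
        default_factory=lambda: {"AFR": 0.8, "EUR": 0.3})
    params: PipelineParams = field(default_factory=PipelineParams)
    stages: tuple[str, ...] = _STAGES

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name!r}: run the {producer!r} stage first")
    return path


def _scenarios(config: RunConfig) -> dict[str, ArmScenario]:
    return multi_arm(config.n_arms, anchor_seed=100)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "params": dataclasses.asdict(config.params),
        "stages": {},
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    scenarios = _scenarios(config)
    for stage in _STAGES:
        if stage not in config.stages:
            continue
        fn = globals()[f"_stage_{stage}"]
        artifacts = fn(config, scenarios)
        manifest["stages"][stage] = {
            "seed": child_seed(config.seed, stage),
            "artifacts": {p.name: _digest(p) for p in artifacts},
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config: RunConfig, scenarios) -> list[Path]:
    out = config.outdir
    seed = child_seed(config.seed, "simulate")
    pop = PopulationSpec(
        frequencies={
            arm: {sp: {f"{arm}_ref": config.ref_hap_frequency.get(sp, 0.5),
                       f"{arm}_noB5":
                       1.0 - config.ref_hap_frequency.get(sp, 0.5)}
                  for sp in config.superpop_sizes}
            for arm in scenarios},
        superpop_sizes=dict(config.superpop_sizes), seed=seed)
    genomes = sample_population(pop)
    meta = pd.DataFrame(
        [{"genome": g.genome_id, "superpop": g.superpop,
          **{f"hap_{arm}": "|".join(g.haplotypes[arm])
             for arm in scenarios}}
         for g in genomes])
    meta.to_csv(out / "cohort.tsv", sep="\t", index=False)
    artifacts = [out / "cohort.tsv"]
    ref_maps, ref_rows = [], []
    for arm, sc in scenarios.items():
        ref_maps.append(sc.reference.map)
        oc = sc.reference.onecopy_interval
        ref_rows.append({
            "arm": arm, "map_id": sc.reference.map.id,
            "tel_end_bp": sc.reference.tel_end_bp,
            "onecopy_start": oc.start if oc else "",
            "onecopy_end": oc.end if oc else "",
            "terminal_gap_bp": (sc.reference.terminal_gap().length
                                if sc.reference.terminal_gap() else 0),
        })
    write_cmap(ref_maps, out / "reference.cmap",
               comments=[f"seed={seed}"])
    pd.DataFrame(ref_rows).to_csv(out / "reference_arms.tsv", sep="\t",
                                  index=False)
    artifacts += [out / "reference.cmap", out / "reference_arms.tsv"]
    molecules: list[SimulatedMolecule] = []
    for g in genomes:
        for arm, sc in scenarios.items():
            h1, h2 = g.haplotypes[arm]
            pair = (sc.haplotypes[h1], sc.haplotypes[h2])
            molecules.extend(simulate_diploid_arm(
                pair, config.params,
                seed=child_seed(seed, f"{g.genome_id}:{arm}"),
                telomere_labeling=True,
                source_prefix=f"{g.genome_id}:{arm}:"))
    write_bnx(molecules, out / "molecules.bnx")
    artifacts.append(out / "molecules.bnx")
    return artifacts


def _group_molecules(molecules: list[SimulatedMolecule]
                     ) -> dict[tuple[str, str], list[SimulatedMolecule]]:
    grouped: dict[tuple[str, str], list[SimulatedMolecule]] = {}
    for m in molecules:
        genome, arm, _ = m.source.split(":", 2)
        grouped.setdefault((genome, arm), []).append(m)
    return grouped


def _stage_assemble(config: RunConfig, scenarios) -> list[Path]:
    out = config.outdir
    molecules = read_bnx(_require(out / "molecules.bnx", "simulate"))
    contig_maps, support_rows, placement_rows = [], [], []
    for (genome, arm), group in sorted(_group_molecules(molecules).items()):
        result = assemble_arm([m.map for m in group], config.params)
        for k, c in enumerate(result.contigs):
            cid = f"{genome}:{arm}:c{k}"
            c.map.id = cid
            contig_maps.append(c.map)
            for pos, sup in zip(c.map.positions, c.support):
                support_rows.append({"contig": cid, "position": int(pos),
                                     "support": int(sup)})
            for mid, (off, end) in c.placements.items():
                placement_rows.append({"contig": cid, "molecule": mid,
                                       "offset": off, "placed_end": end,
                                       "terminus": c.terminus_bp})
    write_cmap(contig_maps, out / "contigs.cmap")
    pd.DataFrame(support_rows).to_csv(out / "contig_support.tsv", sep="\t",
                                      index=False)
    pd.DataFrame(placement_rows).to_csv(out / "contig_placements.tsv",
                                        sep="\t", index=False)
    return [out / "contigs.cmap", out / "contig_support.tsv",
            out / "contig_placements.tsv"]


def _load_contigs(config: RunConfig) -> dict[str, ConsensusMap]:
    out = config.outdir
    maps = read_cmap(_require(out / "contigs.cmap", "assemble"))
    placements = pd.read_csv(
        _require(out / "contig_placements.tsv", "assemble"), sep="\t")
    support = pd.read_csv(_require(out / "contig_support.tsv", "assemble"),
                          sep="\t")
    contigs = {}
    for lmap in maps:
        pl = placements[placements.contig == lmap.id]
        sup = support[support.contig == lmap.id].sort_values("position")
        contigs[lmap.id] = ConsensusMap(
            map=lmap, support=sup.support.to_numpy(dtype=int),
            n_molecules=len(pl), coverage=0.0,
            placements={r.molecule: (float(r.offset), float(r.placed_end))
                        for r in pl.itertuples()},
            terminus_bp=float(pl.terminus.iloc[0]) if len(pl)
            else float(lmap.length_bp))
    return contigs


def _load_reference(config: RunConfig, scenarios) -> list:
    # reference arms are rebuilt from the scenario (they are deterministic);
    # the CMAP on disk is the exchange format for external callers
    return [sc.reference for sc in scenarios.values()]


def _stage_call(config: RunConfig, scenarios) -> list[Path]:
    out = config.outdir
    contigs = _load_contigs(config)
    molecules = read_bnx(_require(out / "molecules.bnx", "simulate"))
    by_ga = _group_molecules(molecules)
    arms = _load_reference(config, scenarios)
    ap = AlignmentParams.from_pipeline(config.params)
    calls: list[armcall.HaplotypeCall] = []
    truth_of_contig = {}
    for cid, contig in sorted(contigs.items()):
        genome, arm_name, _ = cid.split(":", 2)
        group = by_ga.get((genome, arm_name), [])
        call = armcall.call_arm(genome, contig, arms, config.params,
                                molecules=group, align_params=ap)
        calls.append(call)
        sources = [m.source.split(":", 2)[2] for m in group
                   if m.map.id in contig.placements]
        truth_of_contig[cid] = (pd.Series(sources).mode().iloc[0]
                                if sources else "")
    rows = []
    for arm_name in sorted({c.arm for c in calls if c.anchored}):
        arm_calls = [c for c in calls if c.arm == arm_name]
        armcall.cluster_haplotypes(arm_calls, contigs, config.params, ap)
    for c in calls:
        rows.append({
            "genome": c.genome_id, "arm": c.arm, "contig": c.contig_id,
            "anchored": c.anchored,
            "extension_kb": (c.extension_bp / 1e3
                             if c.extension_bp is not None else ""),
            "gap_assessment": c.gap_assessment.value,
            "cluster": c.cluster if c.cluster is not None else "",
            "telomere_confirmed": c.telomere_confirmed,
            "true_haplotype": truth_of_contig.get(c.contig_id, ""),
        })
    pd.DataFrame(rows).to_csv(out / "calls.tsv", sep="\t", index=False)
    summaries = []
    for arm_name in sorted({c.arm for c in calls if c.anchored}):
        s = armcall.summarize_arm([c for c in calls if c.arm == arm_name],
                                  arm=arm_name,
                                  variability_threshold=config.params
                                  .variability_threshold)
        summaries.append({
            "arm": s.arm, "n_represented": s.n_represented,
            "n_failed": s.n_failed,
            "cluster_sizes": ",".join(map(str, s.cluster_sizes)),
            "variability": s.variability.value,
            "extension_range_kb": (f"{s.extension_range_kb[0]:g}"
                                   f"..{s.extension_range_kb[1]:g}"
                                   if s.extension_range_kb else ""),
        })
    pd.DataFrame(summaries).to_csv(out / "arm_summary.tsv", sep="\t",
                                   index=False)
    return [out / "calls.tsv", out / "arm_summary.tsv"]


def _stage_blocks(config: RunConfig, scenarios) -> list[Path]:
    out = config.outdir
    contigs = _load_contigs(config)
    calls = pd.read_csv(_require(out / "calls.tsv", "call"), sep="\t")
    library = default_block_library()
    patterns = blocks_mod.patterns_from_library(library)
    hit_rows = []
    hits_by_ga: dict[tuple[str, str], list] = {}
    for r in calls.itertuples():
        if not r.anchored or r.contig not in contigs:
            continue
        hits = blocks_mod.detect_blocks(contigs[r.contig].map, patterns,
                                        config.params)
        hits_by_ga.setdefault((r.genome, r.arm), []).extend(hits)
        for h in hits:
            hit_rows.append({
                "genome": r.genome, "arm": r.arm, "contig": r.contig,
                "block": h.block, "start_bp": h.start_bp, "end_bp": h.end_bp,
                "orientation": h.orientation, "score": round(h.score, 3),
                "matched_fraction": round(h.matched_fraction, 3)})
    pd.DataFrame(hit_rows).to_csv(out / "block_hits.tsv", sep="\t",
                                  index=False)
    presence = blocks_mod.presence_matrix(hits_by_ga, patterns)
    flat = presence.copy()
    flat.columns = [f"{arm}|{block}" for arm, block in presence.columns]
    flat.to_csv(out / "presence.tsv", sep="\t")
    return [out / "block_hits.tsv", out / "presence.tsv"]


def _stage_popstats(config: RunConfig, scenarios) -> list[Path]:
    out = config.outdir
    flat = pd.read_csv(_require(out / "presence.tsv", "blocks"), sep="\t",
                       index_col=0)
    flat.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split("|", 1)) for c in flat.columns], names=["arm", "block"])
    meta = pd.read_csv(_require(out / "cohort.tsv", "simulate"), sep="\t")
    superpop = dict(zip(meta.genome, meta.superpop))
    freq_frames, anova_rows = [], []
    for block in sorted({b for _, b in flat.columns}):
        table = popstats_mod.block_frequency_table(flat, superpop, block)
        table.columns = ["|".join(c) if isinstance(c, tuple) else c
                         for c in table.columns]
        table.insert(0, "block", block)
        freq_frames.append(table)
        for r in popstats_mod.block_anova_scan(flat, superpop, block):
            anova_rows.append({
                "block": r.block, "arm": r.arm,
                "F": round(r.f_statistic, 4) if not r.degenerate else "",
                "p": r.p_value if not r.degenerate else "",
                "p_bonferroni": r.adjusted_p if r.adjusted_p is not None
                else "", "significant": r.significant,
                "degenerate": r.degenerate})
    freq = pd.concat(freq_frames)
    freq.to_csv(out / "block_frequencies.tsv", sep="\t")
    pd.DataFrame(anova_rows).to_csv(out / "anova.tsv", sep="\t", index=False)
    return [out / "block_frequencies.tsv", out / "anova.tsv"]


# ---------------------------------------------------------------------------
# evaluation against simulation truth

def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings."""
    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b).codes
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    n = len(a)
    if n == 0:
        return 1.0
    table = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_i = comb2(table.sum(axis=1)).sum()
    sum_j = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_i * sum_j / total if total else 0.0
    max_index = (sum_i + sum_j) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def evaluate_against_truth(calls: pd.DataFrame,
                           true_extension: dict[str, int] | None = None
                           ) -> pd.DataFrame:
    """Per-arm agreement between calls and simulation truth.

    ``calls`` is the calls.tsv table (needs ``true_haplotype`` from the
    pipeline); ``true_extension`` maps haplotype name -> planted extension
    (bp).  Reports cluster-vs-truth adjusted Rand index and, when the
    planted extensions are supplied, the mean absolute extension error.
    """
    rows = []
    anchored = calls[calls.anchored.astype(bool)].copy()
    for arm, df in anchored.groupby("arm"):
        labeled = df[(df.cluster != "") & (df.true_haplotype != "")]
        ari = (adjusted_rand_index(labeled.true_haplotype, labeled.cluster)
               if len(labeled) else float("nan"))
        rec = {"arm": arm, "n_contigs": len(df), "cluster_truth_ari": ari}
        if true_extension is not None:
            errs = [abs(float(r.extension_kb) * 1e3
                        - true_extension.get(r.true_haplotype, 0))
                    for r in labeled.itertuples()
                    if r.extension_kb != ""]
            rec["mean_extension_error_kb"] = (np.mean(errs) / 1e3
                                              if errs else float("nan"))
        rows.append(rec)
    return pd.DataFrame(rows)
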