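"""End-to-end orchestration: alignment -> tree -> partition -> trace ->
structure mapping -> binding-site report.

Stages communicate only through files in the output directory, so each is
independently inspectable and re-runnable; a MANIFEST records every output
with a content hash, and a run is byte-reproducible given the same inputs
and configuration.
"""

from __future__ import annotations

import hashlib
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import alignio, phylogeny, structure as st, trace as tr

logger = logging.getLogger("etrace")


@dataclass
class StructureJob:
    """One structure to analyse: where it is, which chain, what the ligand
    is, and which alignment record it corresponds to."""

    id: str
    pdb: str
    chain: str = "A"
    query_id: str = ""
    numbering_offset: int = 1
    ligand_chain: str | None = None
    ligand_resnames: list[str] | None = None
    flap: tuple[int, int] | None = None


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run.

    Defaults follow the reference workflow: 5.0 A inclusive contact cutoff,
    >80% identity selection, chain A.
    """

    msa: str = ""
    msa_format: str = "fasta"
    out_dir: str = "etrace_out"
    cut_edge: str | None = None  # None = automatic deepest-split cut
    structures: list[StructureJob] = field(default_factory=list)
    cutoff: float = 5.0
    identity_threshold: float = 80.0
    min_group_identity: float = 1.0
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        jobs = [StructureJob(**j) for j in raw.pop("structures", [])]
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.structures = jobs
        for job in cfg.structures:
            if job.flap is not None:
                job.flap = tuple(job.flap)  # type: ignore[assignment]
        return cfg


@dataclass
class PipelineReport:
    """What a run produced: output paths, summary numbers, completion state."""

    outputs: dict[str, Path] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    complete: bool = True
    errors: list[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> PipelineReport:
    """Run every stage, writing all outputs under ``config.out_dir``.

    A missing or failing structure stage degrades the run (sequence
    outputs are still produced and the report is marked partial) rather
    than aborting it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()

    logger.info("stage sequence: reading alignment %s", config.msa)
    msa = alignio.read_alignment(config.msa, config.msa_format)

    logger.info("stage phylogeny: p-distances + neighbor joining (n=%d)", len(msa.records))
    dm = phylogeny.p_distance_matrix(msa)
    tree = phylogeny.neighbor_joining(dm)
    tree_path = out / "tree.nwk"
    phylogeny.write_newick(tree, tree_path)
    report.outputs["tree"] = tree_path

    if config.cut_edge:
        partition = phylogeny.partition_at_edge(tree, config.cut_edge)
    else:
        partition = phylogeny.auto_partition(tree, k=2)
    logger.info("stage partition: cut edge %s -> groups of %d/%d", partition.cut_edge,
                len(partition.group(1)), len(partition.group(2)))
    part_path = out / "partition.tsv"
    partition.to_tsv(part_path)
    report.outputs["partition"] = part_path

    logger.info("stage trace: classifying %d columns", msa.length)
    result = tr.EvolutionaryTrace(
        msa, partition, min_group_identity=config.min_group_identity
    ).fit()
    et_path = out / "et_sequence.fasta"
    with open(et_path, "w", newline="\n") as fh:
        fh.write(">ET\n")
        rendering = result.et_sequence
        for i in range(0, len(rendering), 60):
            fh.write(rendering[i : i + 60] + "\n")
    report.outputs["et_sequence"] = et_path
    counts = result.trace.counts()
    report.summary["columns"] = len(result.trace)
    report.summary["column_counts"] = {s.value: n for s, n in counts.items()}

    status_maps: dict[str, tr.ResidueStatusMap] = {}
    for job in config.structures:
        if job.query_id:
            try:
                smap = result.map_to_query(job.query_id, job.numbering_offset)
            except KeyError as exc:
                report.errors.append(f"trace mapping for {job.id}: {exc}")
                report.complete = False
                continue
            status_maps[job.id] = smap
            map_path = out / f"status_map_{job.id}.tsv"
            smap.to_tsv(map_path)
            report.outputs[f"status_map_{job.id}"] = map_path
            fr = tr.status_fractions(smap)
            report.summary[f"status_fractions_{job.id}"] = {
                row["status"]: (int(row["count"]), float(row["percent"]))
                for _, row in fr.iterrows()
            }

    sites: dict[str, st.BindingSite] = {}
    chains: dict[str, st.Structure] = {}
    for job in config.structures:
        try:
            logger.info("stage structure: %s (%s, chain %s)", job.id, job.pdb, job.chain)
            full = st.read_pdb(job.pdb)
            chain = st.select_chain(full, job.chain)
            chains[job.id] = chain
            ligand = st.ligand_selection(
                full, chain=job.ligand_chain, resnames=job.ligand_resnames
            )
            site = st.binding_site(chain, ligand, cutoff=config.cutoff)
            sites[job.id] = site
            site_path = out / f"bindsite_{job.id}.tsv"
            site.to_tsv(site_path)
            report.outputs[f"bindsite_{job.id}"] = site_path
            report.summary[f"binding_site_size_{job.id}"] = len(site)
            if job.id in status_maps:
                annotated = st.annotate_binding_site(site, status_maps[job.id])
                ann_path = out / f"bindsite_annotated_{job.id}.tsv"
                annotated.to_csv(ann_path, sep="\t", index=False, lineterminator="\n")
                report.outputs[f"bindsite_annotated_{job.id}"] = ann_path
                report.summary[f"bindsite_status_counts_{job.id}"] = (
                    annotated["status"].value_counts().to_dict()
                )
                pdb_path = out / f"annotated_{job.id}.pdb"
                st.write_annotated_pdb(chain, status_maps[job.id], pdb_path)
                report.outputs[f"annotated_pdb_{job.id}"] = pdb_path
            if job.flap is not None:
                flap = st.flap_intersection(site, *job.flap)
                report.summary[f"flap_site_{job.id}"] = flap
        except (OSError, st.StructureError) as exc:
            logger.warning("structure stage %s failed: %s", job.id, exc)
            report.errors.append(f"structure stage {job.id}: {exc}")
            report.complete = False

    if len(chains) >= 2:
        ids = [j.id for j in config.structures if j.id in chains][:2]
        sup = st.superpose_chains(chains[ids[0]], chains[ids[1]])
        sup_path = out / "superposition.tsv"
        with open(sup_path, "w", newline="\n") as fh:
            fh.write("structure_a\tstructure_b\trmsd\tn_pairs\n")
            fh.write(f"{ids[0]}\t{ids[1]}\t{sup.rmsd:.3f}\t{sup.n_pairs}\n")
        report.outputs["superposition"] = sup_path
        report.summary["superposition"] = {
            "pair": ids, "rmsd": round(sup.rmsd, 3), "n_pairs": sup.n_pairs
        }

    summary_path = out / "summary.txt"
    with open(summary_path, "w", newline="\n") as fh:
        fh.write(result.summary() + "\n\n")
        for key, value in report.summary.items():
            fh.write(f"{key}: {value}\n")
        if report.errors:
            fh.write("\nerrors:\n")
            for err in report.errors:
                fh.write(f"  {err}\n")
    report.outputs["summary"] = summary_path

    manifest_path = out / "MANIFEST.tsv"
    with open(manifest_path, "w", newline="\n") as fh:
        fh.write(f"# complete: {report.complete}\n")
        fh.write("output\tpath\tsha256\n")
        for key in sorted(report.outputs):
            p = report.outputs[key]
            fh.write(f"{key}\t{p.name}\t{_sha256(p)}\n")
    report.outputs["manifest"] = manifest_path
    return report
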