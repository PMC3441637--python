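"""Manifest-driven end-to-end orchestration.

``load_dataset`` reads and cross-validates every input named in a YAML
manifest; ``run_pipeline`` executes the stage chain

    reliability -> disablers -> ORF calls -> dating -> lineage class ->
    paralog/peptide filters -> shared-disabler curation -> transcription
    calls -> tissue proportions -> profile correlations -> shuffle null ->
    junction classification -> dN/dS

producing a per-gene report with reason codes and a filter-funnel
summary.  A failure in one gene is isolated and reason-coded; it never
aborts the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from denovotx import comparative, dating, evolution, expression, orf_screen, splicing
from denovotx.dating import PresenceProfile
from denovotx.expression import ExpressionMatrix, IntergenicBackground
from denovotx.io import read_alignment_pair, read_tsv
from denovotx.orf_screen import CodonAlignmentPair, OrfCall
from denovotx.phylo import SpeciesTree
from denovotx.splicing import JunctionRecord

logger = logging.getLogger(__name__)

__all__ = ["Params", "Dataset", "ValidationReport", "RunResult",
           "load_manifest", "load_dataset", "run_pipeline"]


@dataclass
class Params:
    """Every tunable threshold, defaulting to the published values."""

    min_coverage: float = 0.70
    min_identity: float = 0.50
    max_fraction_threshold: float = 0.70
    length_unit: str = "aa"
    evalue_cutoff: float = 1e-6
    focal_rpkm_cutoff: float = 0.5
    rpkm_cutoff: float = 0.2
    alpha: float = 0.05
    correlation_cutoff: float = 0.5
    n_sim: int = 10_000
    min_flank_reads: int = 1
    min_span_reads: int = 1
    flank_fraction: float = 0.5
    bins: int = 100
    bidir_window: int = 1000
    seed: Optional[int] = None

    @classmethod
    def from_mapping(cls, mapping: dict) -> "Params":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class ValidationReport:
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class Dataset:
    """Validated in-memory bundle of all pipeline inputs."""

    tree: SpeciesTree
    focal_species: str
    sister_species: str
    genes: List[str]
    alignments: Dict[str, Dict[str, CodonAlignmentPair]]
    locus_profiles: Dict[str, PresenceProfile] = field(default_factory=dict)
    focal_expr: Optional[ExpressionMatrix] = None
    outgroup_expr: Optional[ExpressionMatrix] = None
    expr_species: str = "rhesus"
    background: Optional[IntergenicBackground] = None
    junctions: List[JunctionRecord] = field(default_factory=list)
    hit_tables: Dict[str, List[Sequence]] = field(default_factory=dict)
    proteins: Dict[str, str] = field(default_factory=dict)
    peptides: Dict[str, List[str]] = field(default_factory=dict)
    curation: Dict[str, bool] = field(default_factory=dict)
    dnds_blocks: List[Tuple[str, str]] = field(default_factory=list)
    truth: Optional[dict] = None


@dataclass
class RunResult:
    per_gene: pd.DataFrame
    summary: dict
    null_result: Optional[comparative.NullResult] = None


def load_manifest(path) -> dict:
    with open(path) as handle:
        manifest = yaml.safe_load(handle)
    if not isinstance(manifest, dict):
        raise ValueError("manifest must be a YAML mapping")
    return manifest


def _zero_background(n: int = 1000) -> IntergenicBackground:
    # degenerate null: any positive RPKM is "significant"; used when no
    # intergenic sample is supplied
    return IntergenicBackground(np.zeros(n))


def load_dataset(manifest: dict, base_dir=".") -> Tuple[Optional[Dataset], ValidationReport]:
    """Parse and cross-validate the files referenced by a manifest.

    Returns ``(dataset, report)``; the dataset is None whenever the
    report carries errors.  Failures are enumerated, never silently
    dropped.
    """
    base = Path(base_dir)
    report = ValidationReport()

    def resolve(key: str, required: bool = False) -> Optional[Path]:
        rel = manifest.get(key)
        if rel is None:
            if required:
                report.errors.append(f"manifest key {key!r} missing")
            return None
        path = base / rel
        if not path.exists():
            report.errors.append(f"{key}: file not found: {path}")
            return None
        return path

    tree_path = resolve("tree", required=True)
    tree = None
    if tree_path is not None:
        try:
            tree = SpeciesTree.from_newick(tree_path.read_text())
        except Exception as exc:  # malformed newick
            report.errors.append(f"tree: {exc}")

    focal = manifest.get("focal_species", "human")
    sister = manifest.get("sister_species", "chimp")
    if tree is not None and focal not in tree:
        report.errors.append(f"focal species {focal!r} not in tree")

    alignments: Dict[str, Dict[str, CodonAlignmentPair]] = {}
    aln_dir = resolve("alignments")
    if aln_dir is not None:
        for fasta in sorted(Path(aln_dir).glob("*.fa")):
            try:
                gene, species = fasta.stem.rsplit("__", 1)
                pair = read_alignment_pair(fasta)
            except Exception as exc:
                report.errors.append(f"alignment {fasta.name}: {exc}")
                continue
            if tree is not None and species not in tree:
                report.errors.append(
                    f"alignment {fasta.name}: species {species!r} not in tree"
                )
                continue
            alignments.setdefault(gene, {})[species] = pair
    genes = sorted(alignments)

    locus_profiles: Dict[str, PresenceProfile] = {}
    locus_path = resolve("locus_profiles")
    if locus_path is not None:
        frame = read_tsv(locus_path)
        for gene, grp in frame.groupby("gene"):
            try:
                locus_profiles[str(gene)] = PresenceProfile(
                    entity="locus",
                    states=dict(zip(grp["species"], grp["state"])),
                )
            except (ValueError, KeyError) as exc:
                report.errors.append(f"locus profile for {gene}: {exc}")
        for gene in locus_profiles:
            if gene not in alignments:
                report.errors.append(
                    f"locus profile gene {gene!r} missing from alignments"
                )

    def load_expr(prefix: str, species: str) -> Optional[ExpressionMatrix]:
        rpkm_path = resolve(f"{prefix}_rpkm")
        lib_path = resolve(f"{prefix}_library_sizes")
        if rpkm_path is None or lib_path is None:
            return None
        rpkm = read_tsv(rpkm_path, index_col=0)
        libs = read_tsv(lib_path, index_col=0).iloc[:, 0]
        lengths_path = resolve(f"{prefix}_region_lengths")
        if lengths_path is not None:
            lengths = read_tsv(lengths_path, index_col=0).iloc[:, 0]
        else:
            lengths = pd.Series(1000, index=rpkm.index)
        try:
            return ExpressionMatrix(
                species=species,
                rpkm=rpkm,
                library_sizes=libs,
                region_lengths=lengths,
            )
        except ValueError as exc:
            report.errors.append(f"{prefix} expression: {exc}")
            return None

    expr_species = manifest.get("expression_outgroup", "rhesus")
    focal_expr = load_expr("focal", focal)
    outgroup_expr = load_expr("outgroup", expr_species)
    if focal_expr is not None and outgroup_expr is not None:
        shared = set(focal_expr.tissues) & set(outgroup_expr.tissues)
        for mat in (focal_expr, outgroup_expr):
            dropped = set(mat.tissues) - shared
            if dropped:
                report.warnings.append(
                    f"tissues only in {mat.species}: {sorted(dropped)}; "
                    "dropped from the shared set"
                )

    junctions: List[JunctionRecord] = []
    junc_path = resolve("junctions")
    if junc_path is not None:
        frame = read_tsv(junc_path)
        for _, row in frame.iterrows():
            try:
                junctions.append(
                    JunctionRecord(
                        chrom=str(row["chrom"]),
                        intron_start=int(row["intron_start"]),
                        intron_end=int(row["intron_end"]),
                        strand=str(row["strand"]),
                        spanning_reads=int(row.get("spanning_reads", 0)),
                        donor_flank_cov=int(row.get("donor_flank_cov", 0)),
                        acceptor_flank_cov=int(row.get("acceptor_flank_cov", 0)),
                    )
                )
            except (ValueError, KeyError) as exc:
                report.errors.append(f"junction row {row.to_dict()}: {exc}")

    background = None
    bg_path = resolve("intergenic_rpkm")
    if bg_path is not None:
        values = read_tsv(bg_path)["rpkm"].values
        background = IntergenicBackground(values)

    truth = None
    truth_path = resolve("truth")
    if truth_path is not None:
        truth = json.loads(truth_path.read_text())

    if report.errors:
        return None, report
    dataset = Dataset(
        tree=tree,
        focal_species=focal,
        sister_species=sister,
        genes=genes,
        alignments=alignments,
        locus_profiles=locus_profiles,
        focal_expr=focal_expr,
        outgroup_expr=outgroup_expr,
        expr_species=expr_species,
        background=background,
        junctions=junctions,
        truth=truth,
    )
    return dataset, report


def _screen_gene(
    gene: str,
    pairs: Dict[str, CodonAlignmentPair],
    params: Params,
) -> Dict[str, OrfCall]:
    calls: Dict[str, OrfCall] = {}
    for species, aln in pairs.items():
        if (
            orf_screen.assess_reliability(
                aln, params.min_coverage, params.min_identity
            )
            == "ambiguous"
        ):
            calls[species] = OrfCall(species=species, status="ambiguous")
            continue
        disablers = orf_screen.detect_disablers(aln)
        calls[species] = orf_screen.call_orf_status(
            aln,
            disablers,
            max_fraction_threshold=params.max_fraction_threshold,
            length_unit=params.length_unit,
        )
    return calls


def run_pipeline(dataset: Dataset, params: Optional[Params] = None) -> RunResult:
    """Execute all stages on a validated dataset."""
    params = params or Params()
    rows: List[dict] = []
    background = dataset.background or _zero_background()

    transcribed_focal: Dict[str, bool] = {}
    transcribed_out: Dict[str, bool] = {}
    if dataset.focal_expr is not None:
        for gene in dataset.focal_expr.genes:
            vec = dataset.focal_expr.rpkm.loc[gene]
            transcribed_focal[gene] = bool(
                (vec > params.focal_rpkm_cutoff).any()
            )
    if dataset.outgroup_expr is not None:
        for gene in dataset.outgroup_expr.genes:
            vec = dataset.outgroup_expr.rpkm.loc[gene]
            transcribed_out[gene] = any(
                expression.call_transcription(
                    v, background, params.rpkm_cutoff, params.alpha
                )
                for v in vec
            )

    # profile correlations over genes transcribed in both species
    correlations = pd.DataFrame(columns=["r", "correlated"])
    null_result = None
    if dataset.focal_expr is not None and dataset.outgroup_expr is not None:
        both = [
            g
            for g in dataset.focal_expr.genes
            if transcribed_focal.get(g) and transcribed_out.get(g)
        ]
        tissues = [
            t
            for t in dataset.focal_expr.tissues
            if t in set(dataset.outgroup_expr.tissues)
        ]
        if len(both) >= 2 and len(tissues) >= 3:
            f_prop = _proportion_frame(dataset.focal_expr, both, tissues)
            o_prop = _proportion_frame(dataset.outgroup_expr, both, tissues)
            common = f_prop.index.intersection(o_prop.index)
            f_prop, o_prop = f_prop.loc[common], o_prop.loc[common]
            if len(common) >= 2:
                correlations = comparative.profile_correlations(
                    f_prop, o_prop, cutoff=params.correlation_cutoff
                )
                null_result = comparative.ortholog_shuffle_null(
                    f_prop,
                    o_prop,
                    cutoff=params.correlation_cutoff,
                    n_sim=params.n_sim,
                    seed=params.seed,
                )

    for gene in dataset.genes:
        row: Dict[str, object] = {"gene": gene, "reason": ""}
        try:
            calls = _screen_gene(gene, dataset.alignments[gene], params)
            states = {sp: call.status for sp, call in calls.items()}
            states[dataset.focal_species] = "present"
            orf_profile = PresenceProfile(entity="orf", states=states)
            orf_age = dating.assign_age(dataset.tree, orf_profile)
            locus_profile = dataset.locus_profiles.get(
                gene,
                PresenceProfile(
                    entity="locus",
                    states={sp: "present" for sp in dataset.tree.leaves},
                ),
            )
            locus_age = dating.assign_age(dataset.tree, locus_profile)
            lineage = dating.classify_lineage(
                orf_age,
                locus_age,
                dataset.tree,
                focal_species=dataset.focal_species,
                sister_species=dataset.sister_species,
            )
            shared = orf_screen.shared_ancestral_disablers(calls.values())
            n_absent = sum(1 for c in calls.values() if c.status == "absent")

            paralog = orf_screen.paralog_screen(
                gene,
                dataset.proteins.get(gene, ""),
                dataset.hit_tables.get(gene, []),
                other_proteins={
                    k: v for k, v in dataset.proteins.items() if k != gene
                } or None,
                evalue_cutoff=params.evalue_cutoff,
            ) if gene in dataset.hit_tables or gene in dataset.proteins else None

            peptide_ok = None
            if gene in dataset.peptides and gene in dataset.proteins:
                decoys = [v for k, v in dataset.proteins.items() if k != gene]
                peptide_ok = any(
                    orf_screen.peptide_evidence(
                        pep, dataset.proteins[gene], decoys
                    )
                    == "convincing"
                    for pep in dataset.peptides[gene]
                )

            row.update(
                orf_branch=orf_age.branch,
                orf_status=orf_age.status,
                presence_support=orf_age.presence_support,
                locus_branch=locus_age.branch,
                lineage_class=lineage.value,
                n_outgroups_absent=n_absent,
                n_outgroups_ambiguous=sum(
                    1 for c in calls.values() if c.status == "ambiguous"
                ),
                shared_disablers=";".join(
                    f"{s.kind}@{s.focal_codon}:{','.join(sorted(s.species))}"
                    for s in shared
                ),
                birth_vs_loss_resolved=bool(shared),
                paralog_pass=None if paralog is None else paralog.passed,
                paralog_reason="" if paralog is None else paralog.reason,
                peptide_pass=peptide_ok,
                curation_pass=dataset.curation.get(gene, True),
                transcribed_focal=transcribed_focal.get(gene),
                transcribed_outgroup=transcribed_out.get(gene),
                profile_r=(
                    float(correlations.loc[gene, "r"])
                    if gene in correlations.index
                    else None
                ),
                correlated=(
                    bool(correlations.loc[gene, "correlated"])
                    if gene in correlations.index
                    else None
                ),
            )
        except Exception as exc:  # isolate the failing gene
            logger.exception("gene %s failed", gene)
            row["reason"] = f"stage_failure: {exc}"
            row["lineage_class"] = "rejected"
        rows.append(row)

    if rows:
        per_gene = pd.DataFrame(rows).set_index("gene")
    else:
        per_gene = pd.DataFrame(columns=["lineage_class", "reason"])
        per_gene.index.name = "gene"

    junction_status = [
        splicing.classify_junction(
            j, params.min_flank_reads, params.min_span_reads
        )
        for j in dataset.junctions
    ]

    summary = _summarize(per_gene, junction_status, null_result, params)
    if dataset.dnds_blocks:
        dnds = evolution.merged_dnds(dataset.dnds_blocks)
        summary["merged_dnds"] = {
            "dN": dnds.dN,
            "dS": dnds.dS,
            "ratio": dnds.ratio,
            "n_codons": dnds.n_codons,
        }
    return RunResult(per_gene=per_gene, summary=summary, null_result=null_result)


def _proportion_frame(
    mat: ExpressionMatrix, genes: Sequence[str], tissues: Sequence[str]
) -> pd.DataFrame:
    rows = {}
    for gene in genes:
        prop = expression.tissue_proportions(mat.rpkm.loc[gene, tissues].values)
        if prop is not None:
            rows[gene] = prop
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(tissues)
    )


def _summarize(
    per_gene: pd.DataFrame,
    junction_status: List[str],
    null_result: Optional[comparative.NullResult],
    params: Params,
) -> dict:
    def count(mask) -> int:
        return int(mask.sum()) if len(per_gene) else 0

    dated = per_gene.get("orf_status", pd.Series(dtype=object)) == "dated"
    summary = {
        "n_genes": int(len(per_gene)),
        "n_dated": count(dated),
        "class_counts": (
            per_gene["lineage_class"].value_counts().to_dict()
            if "lineage_class" in per_gene and len(per_gene)
            else {}
        ),
        "n_birth_resolved": count(
            per_gene.get("birth_vs_loss_resolved", pd.Series(dtype=bool)) == True  # noqa: E712
        ),
        "n_transcribed_focal": count(
            per_gene.get("transcribed_focal", pd.Series(dtype=object)) == True  # noqa: E712
        ),
        "n_transcribed_outgroup": count(
            per_gene.get("transcribed_outgroup", pd.Series(dtype=object)) == True  # noqa: E712
        ),
        "n_correlated": count(
            per_gene.get("correlated", pd.Series(dtype=object)) == True  # noqa: E712
        ),
        "junction_status_counts": dict(pd.Series(junction_status).value_counts())
        if junction_status
        else {},
        "params": dataclasses.asdict(params),
    }
    if null_result is not None:
        summary["shuffle_null"] = null_result.to_dict()
    summary["junction_status_counts"] = {
        k: int(v) for k, v in summary["junction_status_counts"].items()
    }
    return summary
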