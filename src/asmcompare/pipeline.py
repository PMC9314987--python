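"""End-to-end orchestration: simulate/load -> align -> synteny -> SV -> SD -> stats.

Every artefact is a plain-text table under the output directory, and a run
manifest records parameters, versions and SHA-256 checksums, so a rerun
with the same configuration and seed is byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .alignkit import (DEFAULT_GAP_TOL, DEFAULT_K, DEFAULT_MIN_BLOCK,
                       align_pair, read_paf, write_paf)
from .chromstats import DEFAULT_NE_FACTOR, deviation_table
from .sdtraffic import (DEFAULT_BOUNDARY_TOL, categorize_direction, classify_sd,
                        find_many_to_one, genes_in_derived, read_genes,
                        remove_sd_insertions, resolve_parent,
                        source_export_table, write_sd_tsv)
from .seqio import AssemblyPair, read_fasta, write_fasta
from .simgenome import SimConfig, simulate_pair, write_truth
from .svclass import (DEFAULT_MIN_LEN, classify_svs, count_by_chromosome,
                      filter_svs, write_sv_tsv, write_sv_vcf)
from .synteny import (DEFAULT_MIN_IDENTITY, gap_fill_stats,
                      gapless_length_ratio, one_to_one_map)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the exit message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    out_dir: str = "results/run"
    fasta_a: str = ""
    fasta_b: str = ""
    paf: str = ""                  # optional precomputed unique alignment
    annotation: str = ""           # optional genes (BED/GFF3), copy-side coords
    x_name: str = "chrX"
    seed: int = 0
    simulate: bool = False         # generate the assembly pair in-process
    k: int = DEFAULT_K
    min_block: int = DEFAULT_MIN_BLOCK
    gap_tol: int = DEFAULT_GAP_TOL
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_len: int = DEFAULT_MIN_LEN
    boundary_tol: int = DEFAULT_BOUNDARY_TOL
    ne_factor: float = DEFAULT_NE_FACTOR

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = line.split("=", 1)
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.strip().lower() in ("1", "true", "yes")
            else:
                kwargs[key] = type(current)(value.strip())
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the artefact bundle plus manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    results: dict = {}

    # --- inputs ----------------------------------------------------------
    truth = None
    if config.simulate:
        sim = SimConfig(seed=config.seed, x_name=config.x_name,
                        sd_counts={"A>A": 2, "A>X": 1, "X>A": 3})
        pair, truth = simulate_pair(sim)
        write_fasta(pair.a, out / "assembly_a.fasta")
        write_fasta(pair.b, out / "assembly_b.fasta")
        write_truth(truth, out / "truth.tsv")
        artifacts += [out / "assembly_a.fasta", out / "assembly_b.fasta",
                      out / "truth.tsv"]
    elif config.fasta_a and config.fasta_b:
        pair = AssemblyPair(
            read_fasta(config.fasta_a, x_name=config.x_name),
            read_fasta(config.fasta_b, x_name=config.x_name),
            x_name=config.x_name,
        )
    else:
        raise PipelineError(
            "input", "either simulate=true or both fasta_a and fasta_b are required")
    results["pair"] = pair
    results["truth"] = truth

    # --- alignment --------------------------------------------------------
    try:
        if config.paf:
            unique_blocks = read_paf(config.paf)
            multi_blocks = unique_blocks
        else:
            unique_blocks, multi_blocks = align_pair(
                pair.a, pair.b, k=config.k, min_block=config.min_block,
                gap_tol=config.gap_tol)
        write_paf(unique_blocks, out / "alignment_unique.paf",
                  pair.a.lengths(), pair.b.lengths())
        write_paf(multi_blocks, out / "alignment_multi.paf",
                  pair.a.lengths(), pair.b.lengths())
        artifacts += [out / "alignment_unique.paf", out / "alignment_multi.paf"]
    except (ValueError, OSError) as exc:
        raise PipelineError("align", str(exc)) from exc

    # --- synteny & continuity --------------------------------------------
    try:
        chains = one_to_one_map(unique_blocks, min_identity=config.min_identity)
        write_paf(chains, out / "synteny.paf", pair.a.lengths(), pair.b.lengths())
        gap_report = gap_fill_stats(pair.a.all_ngaps(), pair.b, chains)
        gap_report.to_frame().to_csv(out / "gap_fill.tsv", sep="\t", index=False)
        lr = gapless_length_ratio(pair.a, pair.b)
        lr.to_csv(out / "length_ratio.tsv", sep="\t", index=False)
        artifacts += [out / "synteny.paf", out / "gap_fill.tsv",
                      out / "length_ratio.tsv"]
        results.update(chains=chains, gap_report=gap_report, length_ratio=lr)
    except (ValueError, OSError) as exc:
        raise PipelineError("synteny", str(exc)) from exc

    # --- segmental duplications (first: SV calls coinciding with derived
    # copies are routed here, keeping the two catalogues disjoint) ---------
    try:
        pairs = find_many_to_one(multi_blocks, min_len=config.min_block,
                                 copy_side="target")
        for p in pairs:
            classify_sd(p, chains, boundary_tol=config.boundary_tol)
            resolve_parent(p, pair.b, pair.a)
    except (ValueError, OSError) as exc:
        raise PipelineError("sdtraffic", str(exc)) from exc

    # --- structural variants ----------------------------------------------
    try:
        svs = filter_svs(
            classify_svs(chains, multi_blocks, pair.a.all_ngaps(),
                         pair.b.all_ngaps()),
            min_len=config.min_len)
        svs = remove_sd_insertions(svs, pairs, min_len=config.min_len)
        write_sv_tsv(svs, out / "svs.tsv")
        write_sv_vcf(svs, out / "svs.vcf", pair.a.lengths())
        sv_table = count_by_chromosome(svs, pair.a.lengths(), config.x_name)
        sv_table.to_csv(out / "sv_counts.tsv", sep="\t")
        artifacts += [out / "svs.tsv", out / "svs.vcf", out / "sv_counts.tsv"]
        results.update(svs=svs, sv_table=sv_table)
    except (ValueError, OSError) as exc:
        raise PipelineError("svclass", str(exc)) from exc

    # --- segmental duplication reporting ----------------------------------
    try:
        write_sd_tsv(pairs, out / "sds.tsv")
        sd_table, sd_summary = categorize_direction(
            pairs, pair.b.lengths(), config.x_name)
        sd_table.to_csv(out / "sd_direction_counts.tsv", sep="\t")
        export_table = source_export_table(pairs, pair.b.lengths(), config.x_name)
        export_table.to_csv(out / "sd_source_exports.tsv", sep="\t")
        artifacts += [out / "sds.tsv", out / "sd_direction_counts.tsv",
                      out / "sd_source_exports.tsv"]
        results.update(sd_pairs=pairs, sd_table=sd_table, sd_summary=sd_summary,
                       sd_exports=export_table)
        if config.annotation:
            genes = read_genes(config.annotation)
            gene_lists = genes_in_derived(pairs, genes,
                                          set(pair.b.chroms))
            with open(out / "derived_copy_genes.tsv", "w") as fh:
                fh.write("family_id\tgenes\n")
                for fam, names in sorted(gene_lists.items()):
                    fh.write(f"{fam}\t{','.join(names)}\n")
            artifacts.append(out / "derived_copy_genes.tsv")
            results["gene_lists"] = gene_lists
    except (ValueError, OSError) as exc:
        raise PipelineError("sdtraffic", str(exc)) from exc

    # --- chromosome statistics --------------------------------------------
    try:
        n_autosomes = sum(1 for c in pair.a.chroms if c != config.x_name)
        if n_autosomes >= 3:
            dev = deviation_table(sv_table, ["DEL", "INS", "DUP", "INV"],
                                  ne_factor=config.ne_factor)
            dev.to_csv(out / "x_deviation.tsv", sep="\t", index=False)
            artifacts.append(out / "x_deviation.tsv")
            results["deviation"] = dev
        else:
            logger.warning("fewer than 3 autosomes; skipping the X regression")
    except (ValueError, OSError) as exc:
        raise PipelineError("chromstats", str(exc)) from exc

    manifest = {
        "tool": "asmcompare",
        "version": __version__,
        "seed": config.seed,
        "parameters": {f.name: getattr(config, f.name)
                       for f in dataclasses.fields(config)},
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
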