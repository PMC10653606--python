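"""End-to-end orchestration: filter -> rates/spectra -> CNV -> LOH ->
condition comparisons, over the canonical on-disk dataset layout.

The pipeline consumes the directory layout written by
:func:`mafoot.simulate.write_simulation` (or assembled by hand from
real tables in the same formats) and writes per-stage TSV reports plus
a JSON manifest recording inputs, parameters, seed and package
version.  Outputs are deterministic given the same inputs and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cnv import call_chromosome_cn, mtdna_estimate, rdna_copy_number, segment_cnv
from .filters import filter_substitutions
from .genome import (
    DepthProfile,
    GenomeDef,
    Interval,
    read_depth_windows,
    read_design,
    read_markers,
    read_variants,
)
from .loh import detect_loh, loh_statistics
from .rates import per_base_rate
from .spectra import SpectrumCounts, gc_at_bias, ts_tv
from .stats import compare_groups

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("mafoot")


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    """Paths and parameter overrides for one pipeline run."""

    data_dir: str | Path
    out_dir: str | Path
    seed: int = 0
    min_windows: int = 20
    cnv_min_windows: int = 10
    cnv_merge_gap: int = 2
    marker_min_depth: int = 10
    het_minor_frac: float = 0.15
    hom_major_frac: float = 0.9
    present_threshold: float = 0.1
    lost_threshold: float = 0.05
    mito_genes: dict[str, tuple[int, int]] = field(default_factory=dict)
    log_level: str = "INFO"


def _mito_gene_intervals(cfg: RunConfig, genome: GenomeDef) -> dict[str, Interval]:
    if genome.mito_name is None:
        return {}
    if cfg.mito_genes:
        return {
            name: Interval(genome.mito_name, s, e)
            for name, (s, e) in cfg.mito_genes.items()
        }
    # default: three 1-kb near repeat-free marker genes spaced along mtDNA
    L = genome.length_of(genome.mito_name)
    out = {}
    for name, fracpos in (("ATP6", 0.10), ("COX2", 0.40), ("COX3", 0.70)):
        s = max(1, int(fracpos * L))
        out[name] = Interval(genome.mito_name, s, min(L, s + 999))
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Writes, under ``out_dir``: ``filter_verdicts.tsv``,
    ``line_summary.tsv``, ``condition_rates.tsv``, ``karyotype.tsv``,
    ``cnv_segments.tsv``, ``rdna_mtdna.tsv``, ``loh_segments.tsv``,
    ``loh_rates.tsv``, ``comparisons.tsv`` and ``manifest.json``.
    """
    logging.basicConfig(level=config.log_level)
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(f"[{name}] {e}") from e
        return deco

    # ---- load ----------------------------------------------------------
    @stage("load")
    def loaded():
        genome = GenomeDef.from_yaml(data / "genome.yaml")
        design = read_design(data / "design.tsv")
        calls = read_variants(data / "variants.tsv", "tsv", genome=genome)
        return genome, design, calls

    genome, design, calls = loaded

    def line_depth(line_id: str) -> DepthProfile:
        safe = line_id.replace("/", "_")
        return DepthProfile(read_depth_windows(data / "depth" / f"{safe}.tsv"))

    # ---- filter --------------------------------------------------------
    @stage("filter")
    def verdicts():
        v = filter_substitutions(calls, genome=genome)
        n_fail = sum(not x.passed for x in v)
        if n_fail:
            log.warning("filter: %d/%d records rejected", n_fail, len(v))
        rows = [
            {
                "line_id": x.variant.line_id,
                "chrom": x.variant.chrom,
                "pos": x.variant.pos,
                "var_type": x.variant.var_type,
                "pass": x.passed,
                "reasons": ",".join(sorted(x.reasons)),
            }
            for x in v
        ]
        pd.DataFrame(
            rows, columns=["line_id", "chrom", "pos", "var_type", "pass", "reasons"]
        ).to_csv(out / "filter_verdicts.tsv", sep="\t", index=False)
        return v

    passed = [x.variant for x in verdicts if x.passed]

    # ---- rates & spectra ----------------------------------------------
    @stage("rates")
    def rate_tables():
        by_line = {ln.line_id: ln for ln in design}
        line_rows = []
        for ln in design:
            subs = [
                c for c in passed
                if c.line_id == ln.line_id and c.var_type == "substitution"
            ]
            inds = [
                c for c in passed
                if c.line_id == ln.line_id and c.var_type != "substitution"
            ]
            est = per_base_rate(
                len(subs), ln.callable_sites, ln.ploidy, ln.total_generations
            )
            line_rows.append({
                "line_id": ln.line_id, "condition": ln.condition,
                "n_substitutions": len(subs), "n_indels": len(inds),
                "sub_rate": est.rate, "sub_rate_ci_low": est.ci_low,
                "sub_rate_ci_high": est.ci_high,
            })
        line_df = pd.DataFrame(line_rows)
        line_df.to_csv(out / "line_summary.tsv", sep="\t", index=False)

        cond_rows = []
        for cond in design.conditions():
            lines = design.by_condition(cond)
            subs = [
                c for c in passed
                if by_line[c.line_id].condition == cond and c.var_type == "substitution"
            ]
            total_gens = sum(l.total_generations for l in lines)
            sites = lines[0].callable_sites
            ploidy = lines[0].ploidy
            est = per_base_rate(len(subs), sites, ploidy, total_gens)
            six = {k: 0 for k in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")}
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            for c in subs:
                r, a = c.ref, c.alt
                if r in "AG":
                    r, a = comp[r], comp[a]
                six[f"{r}>{a}"] += 1
            # re-express as a context-uniform 96 spectrum for the ratios
            spec = SpectrumCounts(
                {f"A[{k}]A": v for k, v in six.items() if v > 0}
            )
            row = {
                "condition": cond, "n_lines": len(lines),
                "n_substitutions": len(subs), "sub_rate": est.rate,
                "sub_rate_ci_low": est.ci_low, "sub_rate_ci_high": est.ci_high,
            }
            try:
                row["ts_tv"] = ts_tv(spec)
            except (ZeroDivisionError, ValueError):
                row["ts_tv"] = float("nan")
            try:
                row["gc_at_bias"] = gc_at_bias(spec)
            except (ZeroDivisionError, ValueError):
                row["gc_at_bias"] = float("nan")
            cond_rows.append(row)
        pd.DataFrame(cond_rows).to_csv(out / "condition_rates.tsv", sep="\t", index=False)
        return line_df

    line_summary = rate_tables

    # ---- CNV -----------------------------------------------------------
    @stage("cnv")
    def cnv_tables():
        kar_rows, seg_rows, rm_rows = [], [], []
        anc = DepthProfile(read_depth_windows(data / "ancestor_depth.tsv"))
        genes = _mito_gene_intervals(config, genome)
        for ln in design:
            prof = line_depth(ln.line_id)
            kar = call_chromosome_cn(
                prof, genome, ln.ploidy, min_windows=config.min_windows
            )
            for chrom in genome.nuclear_chromosomes():
                kar_rows.append({
                    "line_id": ln.line_id, "chrom": chrom,
                    "copy_number": kar.copy_number[chrom],
                    "confidence": kar.confidence[chrom],
                })
            for seg in segment_cnv(
                prof, genome, ln.ploidy,
                min_windows=config.cnv_min_windows, merge_gap=config.cnv_merge_gap,
            ):
                seg_rows.append({
                    "line_id": ln.line_id, "chrom": seg.chrom,
                    "start": seg.start, "end": seg.end,
                    "copy_number": seg.copy_number, "n_windows": seg.n_windows,
                })
            row = {"line_id": ln.line_id}
            if genome.rdna_locus is not None:
                cn12 = kar.cn(genome.rdna_locus.chrom) or ln.ploidy
                est = rdna_copy_number(prof, anc, genome, cn12, ln.ploidy)
                row["rdna_per_sample"] = est.per_sample
                row["rdna_per_chromosome"] = est.per_chrXII
            if genome.mito_name is not None and genes:
                mt = mtdna_estimate(
                    prof, genome, genes,
                    config.present_threshold, config.lost_threshold,
                )
                row["mtdna_copy_number"] = mt.copy_number
                row["mtdna_presence"] = mt.presence_fraction
                row["mtdna_status"] = mt.status
            rm_rows.append(row)
        pd.DataFrame(kar_rows).to_csv(out / "karyotype.tsv", sep="\t", index=False)
        pd.DataFrame(
            seg_rows,
            columns=["line_id", "chrom", "start", "end", "copy_number", "n_windows"],
        ).to_csv(out / "cnv_segments.tsv", sep="\t", index=False)
        pd.DataFrame(rm_rows).to_csv(out / "rdna_mtdna.tsv", sep="\t", index=False)
        return pd.DataFrame(kar_rows)

    karyotypes = cnv_tables

    # ---- LOH -----------------------------------------------------------
    @stage("loh")
    def loh_tables():
        seg_rows = []
        segments = []
        for ln in design:
            safe = ln.line_id.replace("/", "_")
            mpath = data / "markers" / f"{safe}.tsv"
            if not mpath.exists():
                continue
            markers = read_markers(mpath)
            cn = {
                r["chrom"]: r["copy_number"]
                for _, r in karyotypes[karyotypes["line_id"] == ln.line_id].iterrows()
                if pd.notna(r["copy_number"])
            }
            cn = {k: int(v) for k, v in cn.items()}
            for seg in detect_loh(
                markers, ln.line_id, genome, cn, ln.ploidy,
                config.marker_min_depth, config.het_minor_frac,
                config.hom_major_frac,
            ):
                segments.append(seg)
                seg_rows.append({
                    "line_id": seg.line_id, "chrom": seg.chrom,
                    "parent": seg.parent, "start": seg.start, "end": seg.end,
                    "n_markers": seg.n_markers, "class": seg.loh_class,
                })
        pd.DataFrame(
            seg_rows,
            columns=["line_id", "chrom", "parent", "start", "end", "n_markers", "class"],
        ).to_csv(out / "loh_segments.tsv", sep="\t", index=False)

        rate_rows = []
        for cond in design.conditions():
            try:
                st = loh_statistics(segments, design, genome, condition=cond)
            except Exception:
                continue
            mean_frac = (
                sum(st.genome_fraction.values()) / len(st.genome_fraction)
                if st.genome_fraction else float("nan")
            )
            rate_rows.append({
                "condition": cond, "overall_rate": st.overall_rate,
                "interstitial_rate": st.rates["interstitial"],
                "terminal_rate": st.rates["terminal"],
                "chromosome_loss_rate": st.rates["chromosome_loss"],
                "mean_genome_fraction": mean_frac,
            })
        pd.DataFrame(rate_rows).to_csv(out / "loh_rates.tsv", sep="\t", index=False)
        return segments

    loh_tables  # noqa: B018 - executed above

    # ---- condition comparisons ----------------------------------------
    @stage("compare")
    def comparisons():
        rows = []
        conds = design.conditions()
        for i, a in enumerate(conds):
            for b in conds[i + 1 :]:
                va = line_summary[line_summary["condition"] == a]["sub_rate"]
                vb = line_summary[line_summary["condition"] == b]["sub_rate"]
                if len(va) and len(vb):
                    rows.append({
                        "metric": "sub_rate", "group_a": a, "group_b": b,
                        "p_value": compare_groups(va, vb),
                    })
        pd.DataFrame(rows, columns=["metric", "group_a", "group_b", "p_value"]).to_csv(
            out / "comparisons.tsv", sep="\t", index=False
        )

    comparisons  # noqa: B018

    manifest = {
        "package": "mafoot",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("data_dir", "out_dir")
        },
        "inputs": {
            p.name: _checksum(p)
            for p in sorted(data.glob("*.tsv")) + sorted(data.glob("*.yaml"))
        },
        "outputs": {p.name: _checksum(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
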