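"""End-to-end orchestration: simulate -> atac -> states -> expression ->
footprint -> network -> report, driven by one YAML config.

All randomness flows from one root seed through named per-stage substreams,
so skipping a stage never shifts another stage's draws, and reruns with the
same config+seed produce byte-identical outputs (checksums are recorded in
the report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from regland import __version__
from regland.atac_core import (
    call_peaks,
    classify_fragments,
    consensus_peaks,
    count_fragments_in_peaks,
    cut_site_track,
    differential_accessibility,
    tss_metaprofile,
)
from regland.chromatin_states import (
    MARKS,
    classify_nfr_tss,
    fisher_cooccurrence,
    flatten_state_segments,
    nfr_state_overlap,
    state_feature_enrichment,
    state_upset_table,
)
from regland.expression_link import (
    ExpressionMatrix,
    gene_has_nfr,
    nfr_expression_test,
    normalize_counts,
    parse_sample_map,
    read_counts_tsv,
    replicate_correlation,
    row_zscore_log,
)
from regland.footprints import (
    call_bound,
    correct_cuts,
    differential_occupancy,
    fit_bias_model,
    occupancy_table,
    scan_all_motifs,
    score_sites,
)
from regland.genome_io import (
    Interval,
    Peak,
    read_bed,
    read_fasta,
    read_fragments,
    read_gff3,
    read_jaspar_pfm,
    write_intervals,
    merge_pairs,
)
from regland.networks import (
    build_tf_network,
    export_network,
    merge_phenotype_networks,
    subnetwork_from_root,
)
from regland.synthetic_data import (
    SimConfig,
    substream,
    generate_genome,
    write_dataset,
)

_STAGE_KEYS = {"atac", "states", "footprint", "network", "expression"}
_TOP_KEYS = {"simulate", "inputs", "seed", "outdir", "skip_expression"} | _STAGE_KEYS

_STAGE_DEFAULTS: dict[str, dict] = {
    "atac": {"window": 200, "step": 50, "qvalue": 0.05, "effective_genome_size": None},
    "states": {"tss_window": 200},
    "footprint": {"flank": 20, "k": 6, "tau": None, "tau_method": "otsu",
                  "min_score_frac": 0.8, "background_draws": 100},
    "network": {"tss_window": [-2000, 200], "root": None},
    "expression": {"promoter_window": 200},
}


@dataclass
class PipelineConfig:
    """Fully-resolved pipeline configuration."""

    seed: int = 1
    outdir: str = "regland_out"
    simulate: SimConfig | None = None
    inputs: dict | None = None
    skip_expression: bool = False
    stage_params: dict = field(default_factory=dict)

    def resolved_report(self) -> dict:
        rep = {
            "seed": self.seed,
            "outdir": self.outdir,
            "mode": "simulate" if self.simulate is not None else "inputs",
            "skip_expression": self.skip_expression,
            "stages": self.stage_params,
        }
        if self.simulate is not None:
            rep["simulate"] = dataclasses.asdict(self.simulate)
        return rep


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and strictly validate a YAML pipeline config.

    Unknown keys are rejected (no silent ignoring); exactly one of a
    ``simulate`` block or an ``inputs`` block must be present; every
    referenced input file must exist.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return build_config(raw, base_dir=Path(path).parent)


def build_config(raw: dict, base_dir: Path | None = None) -> PipelineConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    has_sim = "simulate" in raw and raw["simulate"] is not None
    has_inputs = "inputs" in raw and raw["inputs"] is not None
    if has_sim == has_inputs:
        raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")

    sim = None
    if has_sim:
        sim_raw = dict(raw["simulate"]) if isinstance(raw["simulate"], dict) else {}
        valid = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(sim_raw) - valid
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        for k in ("mixture_weights", "mixture_means", "mixture_sds", "phenotypes"):
            if k in sim_raw and isinstance(sim_raw[k], list):
                sim_raw[k] = tuple(sim_raw[k])
        sim = SimConfig(**sim_raw)

    inputs = None
    if has_inputs:
        inputs = dict(raw["inputs"])
        required = {"fasta", "gff", "motifs", "fragments", "chip", "tf_map"}
        missing = required - set(inputs)
        if missing:
            raise ValueError(f"inputs block missing keys: {sorted(missing)}")
        for p in _iter_input_paths(inputs):
            fp = Path(p) if base_dir is None else base_dir / p
            if not fp.exists():
                raise FileNotFoundError(f"configured input does not exist: {fp}")

    stage_params = {}
    for stage, defaults in _STAGE_DEFAULTS.items():
        given = raw.get(stage) or {}
        unknown = set(given) - set(defaults)
        if unknown:
            raise ValueError(f"unknown {stage} keys: {sorted(unknown)}")
        stage_params[stage] = {**defaults, **given}

    return PipelineConfig(
        seed=int(raw.get("seed", 1)),
        outdir=str(raw.get("outdir", "regland_out")),
        simulate=sim,
        inputs=inputs,
        skip_expression=bool(raw.get("skip_expression", False)),
        stage_params=stage_params,
    )


def _iter_input_paths(inputs: dict):
    for key in ("fasta", "gff", "motifs", "tf_map", "counts"):
        if inputs.get(key):
            yield inputs[key]
    for paths in (inputs.get("fragments") or {}).values():
        yield from paths
    for per_ph in (inputs.get("chip") or {}).values():
        for paths in per_ph.values():
            yield from paths


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, log=print) -> dict:
    """Run every stage and return the machine-readable report dict.

    Stage outputs land under ``config.outdir``; the report (also written as
    report.json) carries per-phenotype NFR counts, the percentage of genes
    with >= 1 NFR, TSS/non-TSS state tables, top-10 occupancy, differential
    summaries, network files and output checksums.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.resolved_report(),
    }

    # --- stage: simulate / load -------------------------------------------
    log("[regland] stage: inputs")
    if config.simulate is not None:
        ds = generate_genome(config.simulate, config.seed)
        data_dir = out / "data"
        paths = write_dataset(ds, data_dir)
        genome = dict(ds.sequences)
        annotation = ds.annotation
        motifs = list(ds.motifs)
        tf_gene_map = dict(ds.manifest.tf_gene_map)
        phenotypes = list(config.simulate.phenotypes)
        replicates = config.simulate.replicates
        frag_paths = {
            ph: [paths[f"fragments_{ph}_rep{r}"] for r in range(1, replicates + 1)]
            for ph in phenotypes
        }
        chip_paths = {
            mark: {
                ph: [paths[f"chip_{mark}_{ph}_rep{r}"] for r in (1, 2)]
                for ph in phenotypes
            }
            for mark in MARKS
        }
        counts_path = paths["counts"]
        genome_size = sum(annotation.chrom_sizes.values())
    else:
        inp = config.inputs
        genome = read_fasta(inp["fasta"])
        annotation = read_gff3(inp["gff"])
        for chrom, seq in genome.items():
            annotation.chrom_sizes.setdefault(chrom, len(seq))
        motifs = read_jaspar_pfm(inp["motifs"])
        tf_gene_map = _read_tf_map(inp["tf_map"])
        frag_paths = {ph: [Path(p) for p in v] for ph, v in inp["fragments"].items()}
        phenotypes = sorted(frag_paths)
        chip_paths = {
            mark: {ph: [Path(p) for p in v] for ph, v in per.items()}
            for mark, per in inp["chip"].items()
        }
        counts_path = inp.get("counts")
        genome_size = sum(annotation.chrom_sizes.values())

    atac_p = config.stage_params["atac"]
    egs = atac_p["effective_genome_size"] or genome_size
    chrom_sizes = annotation.chrom_sizes

    # --- stage: atac --------------------------------------------------------
    log("[regland] stage: atac")
    nfr_consensus: dict[str, list[Peak]] = {}
    nfr_frags: dict[str, list] = {}
    nfr_by_sample: dict[str, list] = {}
    class_counts: dict[str, dict[str, int]] = {}
    for ph in phenotypes:
        rep_peaks = []
        pooled_nfr = []
        counts = {c: 0 for c in ("nfr", "mono", "di", "unassigned")}
        for rep_i, path in enumerate(frag_paths[ph], start=1):
            frags = read_fragments(path)
            classes = classify_fragments(frags)
            for c in counts:
                counts[c] += len(classes[c])
            rep_peaks.append(
                call_peaks(classes["nfr"], egs, chrom_sizes,
                           window=atac_p["window"], step=atac_p["step"],
                           q_threshold=atac_p["qvalue"])
            )
            pooled_nfr.extend(classes["nfr"])
            nfr_by_sample[f"{ph}_rep{rep_i}"] = classes["nfr"]
        consensus = consensus_peaks(rep_peaks[0], rep_peaks[1]) if len(rep_peaks) > 1 else rep_peaks[0]
        nfr_consensus[ph] = consensus
        nfr_frags[ph] = pooled_nfr
        class_counts[ph] = counts
        write_intervals(consensus, out / f"nfr_consensus_{ph}.narrowPeak", "narrowPeak")
        track = cut_site_track(pooled_nfr, chrom_sizes)
        profile = tss_metaprofile(track, annotation)
        np.savetxt(out / f"tss_metaprofile_{ph}.tsv", profile.values, fmt="%.6g")

    # union peak set for differential accessibility
    union_pairs: dict[str, list[tuple[int, int]]] = {}
    for ph in phenotypes:
        for p in nfr_consensus[ph]:
            union_pairs.setdefault(p.chrom, []).append((p.start, p.end))
    union_peaks = [
        Peak(Interval(c, s, e), name=f"u_{c}_{s}")
        for c in sorted(union_pairs)
        for s, e in merge_pairs(union_pairs[c])
    ]
    sample_names: list[str] = []
    count_cols = []
    for ph in phenotypes:
        for rep_i in range(1, len(frag_paths[ph]) + 1):
            name = f"{ph}_rep{rep_i}"
            count_cols.append(count_fragments_in_peaks(nfr_by_sample[name], union_peaks))
            sample_names.append(name)
    count_matrix = np.column_stack(count_cols) if count_cols else np.zeros((0, 0))
    pd.DataFrame(count_matrix, index=[p.name for p in union_peaks], columns=sample_names).to_csv(
        out / "nfr_union_counts.tsv", sep="\t"
    )

    diff_access = {}
    for a, b in _pairs(phenotypes):
        cols = [i for i, s in enumerate(sample_names) if s.startswith(f"{a}_") or s.startswith(f"{b}_")]
        labels = [sample_names[i].split("_rep")[0] for i in cols]
        results = differential_accessibility(
            count_matrix[:, cols], labels, unit_ids=[p.name for p in union_peaks]
        )
        sig = [r for r in results if r.q_value <= 0.05]
        diff_access[f"{a}_vs_{b}"] = {"n_tested": len(results), "n_significant": len(sig)}
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / f"diff_accessibility_{a}_vs_{b}.tsv", sep="\t", index=False
        )

    genes_with_nfr = {}
    for ph in phenotypes:
        flags = gene_has_nfr(annotation, nfr_consensus[ph])
        genes_with_nfr[ph] = round(100.0 * sum(flags.values()) / max(len(flags), 1), 4)

    report["atac"] = {
        "fragment_classes": class_counts,
        "n_consensus_nfr_peaks": {ph: len(nfr_consensus[ph]) for ph in phenotypes},
        "pct_genes_with_nfr": genes_with_nfr,
        "differential_accessibility": diff_access,
    }

    # --- stage: states ------------------------------------------------------
    log("[regland] stage: states")
    states_p = config.stage_params["states"]
    state_report = {}
    segments_by_ph = {}
    for ph in phenotypes:
        mark_consensus = {}
        for mark in sorted(chip_paths):
            reps = chip_paths[mark][ph]
            peaks = [read_bed(p) for p in reps]
            mark_consensus[mark] = consensus_peaks(peaks[0], peaks[1])
        segments = flatten_state_segments(mark_consensus)
        segments_by_ph[ph] = segments
        upset = state_upset_table(segments)
        upset.to_csv(out / f"state_upset_{ph}.tsv", sep="\t", index=False)
        enr = state_feature_enrichment(segments, annotation)
        enr.to_csv(out / f"state_feature_enrichment_{ph}.tsv", sep="\t")
        with open(out / f"state_segments_{ph}.bed", "w") as fh:
            for seg in segments:
                fh.write(
                    f"{seg.interval.chrom}\t{seg.interval.start}\t{seg.interval.end}\t{seg.label}\n"
                )

        labels = classify_nfr_tss(nfr_consensus[ph], annotation, window=states_p["tss_window"])
        table = nfr_state_overlap(nfr_consensus[ph], labels, segments)
        table.to_csv(out / f"nfr_state_table_{ph}.tsv", sep="\t", index=False)

        # bp-weighted co-occurrence of the two promoter-associated marks
        n11 = n10 = n01 = 0
        for s in segments:
            bp = len(s.interval)
            if "H3K4me3" in s.marks and "H3K27ac" in s.marks:
                n11 += bp
            elif "H3K4me3" in s.marks:
                n10 += bp
            elif "H3K27ac" in s.marks:
                n01 += bp
        n00 = genome_size - n11 - n10 - n01
        if segments:
            odds, pval = fisher_cooccurrence(n11, n10, n01, n00)
        else:
            odds, pval = float("nan"), float("nan")
        state_report[ph] = {
            "n_segments": len(segments),
            "n_tss_nfr": labels.count("tss"),
            "n_non_tss_nfr": labels.count("non_tss"),
            "k4me3_k27ac_odds_ratio": None if np.isnan(odds) else round(odds, 4),
            "k4me3_k27ac_p": None if np.isnan(pval) else float(pval),
        }
    report["states"] = state_report

    # --- stage: expression --------------------------------------------------
    if not config.skip_expression and counts_path is not None:
        log("[regland] stage: expression")
        expr_raw = read_counts_tsv(counts_path)
        expr = normalize_counts(expr_raw)
        expr_report = {}
        tf_genes = sorted(set(tf_gene_map.values()) & set(expr.values.index))
        for ph in phenotypes:
            ph_cols = [c for c in expr.values.columns if expr.sample_map[c][0] == ph]
            flags = gene_has_nfr(annotation, nfr_consensus[ph],
                                 promoter_window=config.stage_params["expression"]["promoter_window"])
            u, p, med = nfr_expression_test(expr.values[ph_cols], flags)
            rho = (
                replicate_correlation(
                    np.log1p(expr_raw.values[ph_cols[0]]), np.log1p(expr_raw.values[ph_cols[1]])
                )
                if len(ph_cols) >= 2
                else None
            )
            expr_report[ph] = {
                "nfr_expression_U": u,
                "nfr_expression_p": p,
                "median_log_expr_nfr": round(med["nfr"], 4),
                "median_log_expr_other": round(med["other"], 4),
                "replicate_spearman": None if rho is None else round(rho, 4),
            }
        if tf_genes:
            z = row_zscore_log(expr, tf_genes)
            z.to_csv(out / "tf_expression_zscores.tsv", sep="\t")
        report["expression"] = expr_report

    # --- stage: footprint -----------------------------------------------------
    log("[regland] stage: footprint")
    fp_p = config.stage_params["footprint"]
    sites = scan_all_motifs(genome, motifs, union_peaks, min_score_frac=fp_p["min_score_frac"])
    calls_by_ph = {}
    occupancy = {}
    taus = {}
    for ph in phenotypes:
        track = cut_site_track(nfr_frags[ph], chrom_sizes)
        model = fit_bias_model(track, genome, k=fp_p["k"])
        corrected = correct_cuts(track, model, genome)
        calls = score_sites(corrected, sites, flank_bp=fp_p["flank"], phenotype=ph)
        calls, tau = call_bound(calls, method=fp_p["tau_method"], tau=fp_p["tau"])
        calls_by_ph[ph] = calls
        taus[ph] = round(tau, 4)
        occ = occupancy_table(calls, nfr_peaks=nfr_consensus[ph])
        occ.to_csv(out / f"occupancy_{ph}.tsv", sep="\t", index=False)
        occupancy[ph] = occ.head(10).to_dict(orient="records")
        _write_calls(calls, out / f"footprints_{ph}.tsv")

    diff_occ = {}
    for a, b in _pairs(phenotypes):
        dseed = int(substream(config.seed, "diffocc", a, b).integers(0, 2**31 - 1))
        table = differential_occupancy(
            calls_by_ph[a], calls_by_ph[b],
            n_background_draws=fp_p["background_draws"], seed=dseed,
        )
        table.to_csv(out / f"diff_occupancy_{a}_vs_{b}.tsv", sep="\t", index=False)
        diff_occ[f"{a}_vs_{b}"] = {
            "top_motifs_by_p": table["motif"].head(3).tolist(),
            "n_q05": int((table["q_value"] <= 0.05).sum()),
        }
    report["footprint"] = {
        "n_motif_sites": len(sites),
        "tau": taus,
        "n_bound": {ph: sum(c.bound for c in calls_by_ph[ph]) for ph in phenotypes},
        "top10_occupancy": occupancy,
        "differential_occupancy": diff_occ,
    }

    # --- stage: network -------------------------------------------------------
    log("[regland] stage: network")
    net_p = config.stage_params["network"]
    tw = tuple(net_p["tss_window"])
    per_ph_edges = {
        ph: build_tf_network(
            [c for c in calls_by_ph[ph] if c.bound], annotation, tf_gene_map, tss_window=tw
        )
        for ph in phenotypes
    }
    combined = merge_phenotype_networks(per_ph_edges)
    export_network(combined, out / "tf_network.tsv", "tsv")
    export_network(combined, out / "tf_network.dot", "dot")
    net_report = {
        "n_edges_combined": len(combined),
        "n_nodes_combined": len(
            {e.source_tf for e in combined} | {e.target_tf for e in combined}
        ),
        "n_edges_per_phenotype": {ph: len(per_ph_edges[ph]) for ph in phenotypes},
        "edge_classes": {
            cls: sum(e.edge_class == cls for e in combined)
            for cls in ("tss", "non_tss", "both")
        },
    }
    root = net_p["root"]
    if root:
        sub = subnetwork_from_root(combined, root)
        export_network(sub, out / f"tf_network_from_{root}.tsv", "tsv")
        net_report["root_subnetwork_edges"] = len(sub)
    report["network"] = net_report

    # --- report ----------------------------------------------------------------
    report["checksums"] = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(out.rglob("*"))
        if f.is_file() and f.name != "report.json"
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    log("[regland] done")
    return report


def _pairs(items):
    return [(a, b) for i, a in enumerate(items) for b in items[i + 1 :]]


def _write_calls(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmotif\tstrand\tscore\tfs\tbound\tphenotype\n")
        for c in calls:
            iv = c.site.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.site.motif_id}\t{iv.strand}\t"
                f"{c.site.score:.4f}\t{c.fs:.6f}\t{int(c.bound)}\t{c.phenotype}\n"
            )


def read_calls(path):
    """Read a footprints TSV back into FootprintCall records."""
    from regland.footprints import FootprintCall, MotifSite

    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            site = MotifSite(
                cols[idx["motif"]],
                Interval(cols[idx["chrom"]], int(cols[idx["start"]]),
                         int(cols[idx["end"]]), cols[idx["strand"]]),
                float(cols[idx["score"]]),
            )
            calls.append(
                FootprintCall(site, float(cols[idx["fs"]]),
                              bool(int(cols[idx["bound"]])), cols[idx["phenotype"]])
            )
    return calls


def _read_tf_map(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 2 and cols[0] != "motif":
                out[cols[0]] = cols[1]
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
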