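"""End-to-end orchestration: simulate -> enrich -> motif -> maz-scan -> rip -> splice.

Each requested stage writes one TSV result table with a fixed column order,
and a plain-text run log records the configuration, the seed, and per-stage
record counts.  Any stage failure aborts the run with the stage name and the
original cause.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import enrichment, motif, rip, splicing
from .config import AnalysisConfig
from .containers import ExpressionMatrix
from .errors import PipelineError
from . import io as nio
from . import simulate as sim

ALL_STAGES = ("simulate", "enrich", "motif", "maz-scan", "rip", "splice")


def _maz_table(records, n_min, n_max) -> pd.DataFrame:
    rows = []
    for r in records:
        seq = r.premir_seq or r.mature_seq
        for h in motif.maz_scan(seq, n_min, n_max):
            rows.append({"name": r.name, "start": h.start, "n": h.n,
                         "matched": h.matched})
    return pd.DataFrame(rows, columns=["name", "start", "n", "matched"])


def run_pipeline(config: AnalysisConfig, out_dir,
                 stages=ALL_STAGES, expression: ExpressionMatrix | None = None,
                 log_stream=None) -> dict:
    """Run the requested stages on simulated data (or a provided matrix).

    Returns a dict of in-memory stage results; writes one TSV per stage under
    ``out_dir`` plus ``run.log``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError("setup", ValueError(f"unknown stage(s): {sorted(unknown)}"))
    results: dict = {}
    log_lines = [f"seed={config.rng_seed}"]
    log_lines += [f"config.{k}={v}" for k, v in sorted(config.to_dict().items())]
    seed = config.rng_seed

    def stage(name):
        def deco(fn):
            if name in stages:
                try:
                    count = fn()
                except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                    raise PipelineError(name, exc) from exc
                log_lines.append(f"stage={name} records={count}")
            return fn
        return deco

    @stage("simulate")
    def _simulate():
        m, truth = sim.gen_expression(seed=seed)
        records, mir_truth = sim.gen_mirna_set(seed=seed)
        premirs = [
            sim.gen_premir(element_n=3, name="sim-pre-a", seed=seed),
            sim.gen_premir(element_n=2, name="sim-pre-b", seed=seed + 1),
            sim.gen_premir(element_n=None, name="sim-pre-c", seed=seed + 2),
        ]
        enriched = [r for r in records if r.name.startswith("nuc-")]
        t1, t2, utrs, rip_truth = sim.gen_rip_dataset(mirnas=enriched, seed=seed)
        exons, splice_truth = sim.gen_exon_table(seed=seed)
        nio.write_expression_tsv(m, out / "expression.tsv")
        nio.write_fasta(records, out / "mirnas.fasta")
        nio.write_fasta(premirs, out / "premirs.fasta", which="premir")
        nio.write_counts_tsv(t1, out / "counts_ago1.tsv")
        nio.write_counts_tsv(t2, out / "counts_ago2.tsv")
        nio.write_utr_fasta(utrs, out / "utrs.fasta")
        nio.write_exon_tsv(exons, out / "exons.tsv")
        pd.DataFrame({"probe_id": sorted(truth.enriched_probe_ids)}).to_csv(
            out / "truth_enriched_probes.tsv", sep="\t", index=False)
        results.update(expression=m, mirnas=records, premirs=premirs,
                       counts_ago1=t1, counts_ago2=t2, utrs=utrs, exons=exons,
                       truth={"expression": truth, "mirna": mir_truth,
                              "rip": rip_truth, "splice": splice_truth})
        return len(m.signals)

    @stage("enrich")
    def _enrich():
        m = expression if expression is not None else results.get("expression")
        if m is None:
            raise ValueError("enrich requested without an expression matrix "
                             "(provide one or include the simulate stage)")
        table = enrichment.enrichment_table(m, config)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        results["enrichment"] = table
        return len(table)

    @stage("motif")
    def _motif():
        records = results.get("mirnas")
        if records is None:
            raise ValueError("motif stage needs simulated miRNA records")
        enriched = [r for r in records if r.name.startswith("nuc-")]
        background = [r for r in records if not r.name.startswith("nuc-")]
        found = motif.find_recurrent_motif(enriched, config.motif_k)
        rows = []
        for res in found:
            table = motif.motif_contingency(enriched, background, res.motif)
            rows.append({
                "motif": res.motif,
                "support_enriched": table.a, "n_enriched": table.a + table.b,
                "support_background": table.c, "n_background": table.c + table.d,
                "fisher_p": motif.fisher_exact(table, "greater"),
            })
        df = pd.DataFrame(rows, columns=["motif", "support_enriched", "n_enriched",
                                         "support_background", "n_background",
                                         "fisher_p"])
        df.to_csv(out / "motif.tsv", sep="\t", index=False)
        results["motif"] = df
        return len(df)

    @stage("maz-scan")
    def _maz():
        premirs = results.get("premirs")
        if premirs is None:
            raise ValueError("maz-scan stage needs precursor records")
        df = _maz_table(premirs, config.maz_n_min, config.maz_n_max)
        df.to_csv(out / "maz_hits.tsv", sep="\t", index=False)
        results["maz"] = df
        return len(df)

    @stage("rip")
    def _rip():
        if "counts_ago1" not in results:
            raise ValueError("rip stage needs simulated count tables")
        enriched = [r for r in results["mirnas"] if r.name.startswith("nuc-")]
        f1 = rip.filter_counts(results["counts_ago1"], config.count_floor)
        f2 = rip.filter_counts(results["counts_ago2"], config.count_floor)
        map1 = rip.targets_of_enriched(f1, enriched, results["utrs"])
        map2 = rip.targets_of_enriched(f2, enriched, results["utrs"])
        part = rip.partition_targets(set(map1), set(map2))
        pd.DataFrame(
            [{"gene_id": g, "set": label}
             for label, genes in (("unique_ago1", part.unique_ago1),
                                  ("unique_ago2", part.unique_ago2),
                                  ("shared", part.shared))
             for g in sorted(genes)],
            columns=["gene_id", "set"],
        ).to_csv(out / "rip_partition.tsv", sep="\t", index=False)
        merged = {g: map1.get(g, set()) | map2.get(g, set())
                  for g in set(map1) | set(map2)}
        pd.DataFrame(
            [{"gene_id": g, "mirnas": ",".join(sorted(ms))}
             for g, ms in sorted(merged.items())],
            columns=["gene_id", "mirnas"],
        ).to_csv(out / "rip_target_map.tsv", sep="\t", index=False)
        results["rip_partition"] = part
        results["rip_target_map"] = merged
        return len(part.unique_ago1) + len(part.unique_ago2) + len(part.shared)

    @stage("splice")
    def _splice():
        exons = results.get("exons")
        if exons is None:
            raise ValueError("splice stage needs an exon table")
        res = splicing.analyze_splicing(exons, config.fdr_alpha, config.si_threshold)
        res.to_csv(out / "splicing.tsv", sep="\t", index=False)
        flagged = splicing.flag_spliced(res)
        pd.DataFrame({"transcript_id": sorted(flagged)}).to_csv(
            out / "flagged_transcripts.tsv", sep="\t", index=False)
        target_map = results.get("rip_target_map", {})
        pairs = splicing.pair_with_mirna(flagged, target_map)
        pd.DataFrame(pairs, columns=["mirna", "transcript_id"]).to_csv(
            out / "pairings.tsv", sep="\t", index=False)
        results["splicing"] = res
        results["flagged"] = flagged
        return len(res)

    log_text = "\n".join(log_lines) + "\n"
    (out / "run.log").write_text(log_text)
    if log_stream is not None:
        log_stream.write(log_text)
    return results
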