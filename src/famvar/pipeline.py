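"""End-to-end runner chaining all filter stages in the study's order:

region restriction -> SNP QC / indel zygosity recall -> protein-disrupting
filter -> population-database cascade -> dominant shared filter ->
co-segregation -> predictor-consensus prioritization -> case-control
association. Emits the per-stage cascade report, the candidate and ranked
lists, association results, and a log of every threshold actually used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import assoc as fassoc
from .consequence import filter_protein_disrupting
from .core import CascadeReport, QCThresholds
from .inheritance import cosegregation_check, dominant_shared_filter
from .popfilter import DEFAULT_ORDER, cascade_survivors, run_cascade
from .prioritize import (DEFAULT_CONSERVATION_BONUS, DEFAULT_GERP_CONSERVED,
                         ScoreRecord, consensus_score, rank_candidates)
from .simulate import Bundle
from .variant_qc import call_indel_zygosity, qc_snv, restrict_to_targets


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and record context."""


@dataclass
class PipelineResult:
    report: CascadeReport
    candidates: list[str]                 # survivors of co-segregation
    coseg_failures: dict[str, list[str]]  # failing key -> carrier relatives
    ranked: list[ScoreRecord]
    panel_counts: dict[str, fassoc.PanelCounts]
    assoc_results: dict[str, fassoc.AssocResult]
    log: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.report.to_frame().to_csv(outdir / "cascade_report.tsv",
                                      sep="\t", index=False)
        with open(outdir / "cascade_report.json", "w") as fh:
            json.dump({"stages": [{"label": label, "counts": counts}
                                  for label, counts in self.report.stages]},
                      fh, indent=1, sort_keys=True)
        pd.DataFrame({"key": self.candidates}).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"key": k, "carriers": ",".join(v)}
             for k, v in sorted(self.coseg_failures.items())]
        ).to_csv(outdir / "coseg_failures.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(r) for r in self.ranked]).to_csv(
            outdir / "ranked.tsv", sep="\t", index=False)
        rows = []
        for key in self.candidates:
            if key not in self.assoc_results:
                continue
            c = self.panel_counts[key]
            r = self.assoc_results[key]
            rows.append({
                "key": key, "case_carriers": c.case_carriers,
                "control_carriers": c.control_carriers,
                "case_alt": c.case_alt_alleles,
                "case_alleles": c.case_total_alleles,
                "control_alt": c.control_alt_alleles,
                "control_alleles": c.control_total_alleles,
                "chi2": "" if r.chi2 is None else r.chi2,
                "p": "" if r.p is None else r.p,
                "odds_ratio": "" if r.odds_ratio is None else r.odds_ratio,
                "or_corrected": r.or_corrected,
                "reason": r.reason or ""})
        pd.DataFrame(rows).to_csv(outdir / "assoc.tsv", sep="\t",
                                  index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(self.log, fh, indent=1, sort_keys=True)


def run_pipeline(bundle: Bundle,
                 thresholds: QCThresholds = QCThresholds(),
                 db_order: Sequence[str] = DEFAULT_ORDER,
                 gerp_conserved_threshold: float = DEFAULT_GERP_CONSERVED,
                 conservation_bonus: float = DEFAULT_CONSERVATION_BONUS,
                 include_family_cases: bool = True,
                 out_dir: Optional[str] = None) -> PipelineResult:
    """Run every stage on an input bundle; returns the full result.

    ``include_family_cases`` folds the affected exome-sequenced carriers
    into the case side of the association table alongside the sporadic
    panel cases (the reading of the case-control validation that the
    genotyped carrier accounting supports).
    """
    quartet = (bundle.roles["exome_cases"]
               + bundle.roles["exome_controls"])
    cases = bundle.roles["exome_cases"]
    controls = bundle.roles["exome_controls"]
    report = CascadeReport()

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    def carrier_counts(records, genotypes=None):
        counts = {s: 0 for s in quartet}
        for rec in records:
            for s in quartet:
                if genotypes is None:
                    zyg = rec.genotypes[s].zygosity
                else:
                    zyg = genotypes[rec.key][s]
                if zyg in ("het", "hom_alt"):
                    counts[s] += 1
        return counts

    # stage 0: raw input ----------------------------------------------------
    records = bundle.records
    report.add_stage("total", carrier_counts(records))

    # stage 1: target-region restriction ------------------------------------
    records, n_off = stage("target restriction", lambda: restrict_to_targets(
        records, bundle.targets, flank=thresholds.target_flank_bp))
    report.add_stage("within target regions", carrier_counts(records))

    # stage 2: SNP QC and indel zygosity recall -----------------------------
    def run_qc():
        genotypes: dict[str, dict[str, str]] = {}
        for rec in records:
            gts = {}
            for s in quartet:
                zyg = rec.genotypes[s].zygosity
                if rec.site.is_indel:
                    if zyg in ("het", "hom_alt"):
                        support = rec.indel_support.get(s)
                        if support is None:
                            zyg = "missing"
                        else:
                            call, _ = call_indel_zygosity(support, thresholds)
                            zyg = {"het": "het", "hom": "hom_alt",
                                   "no_call": "missing"}[call]
                else:
                    if not qc_snv(rec.qualities[s], thresholds).passed:
                        zyg = "missing"
                gts[s] = zyg
            genotypes[rec.key] = gts
        return genotypes

    genotypes = stage("quality control", run_qc)
    report.add_stage("quality-passing", carrier_counts(records, genotypes))

    # stage 3: protein-disrupting filter ------------------------------------
    def run_pd():
        annotated = []
        for rec in records:
            if rec.key not in bundle.annotations:
                raise KeyError(f"no consequence annotation for {rec.key}")
            annotated.append((rec, bundle.annotations[rec.key][0]))
        return [rec for rec, _ in filter_protein_disrupting(annotated)]

    records_pd = stage("protein-disrupting filter", run_pd)
    report.add_stage("protein-disrupting (PDSI)",
                     carrier_counts(records_pd, genotypes))

    # stage 4: population-database cascade ----------------------------------
    def run_db():
        streams = {s: [rec.key for rec in records_pd
                       if genotypes[rec.key][s] in ("het", "hom_alt")]
                   for s in quartet}
        _, stages = run_cascade(streams, bundle.popdb, order=db_order,
                                threshold=thresholds.af_reject_threshold)
        survivors = cascade_survivors([r.key for r in records_pd],
                                      bundle.popdb, order=db_order,
                                      threshold=thresholds.af_reject_threshold)
        return survivors, stages

    survivors, db_stages = stage("database cascade", run_db)
    for label, counts in db_stages:
        report.add_stage(label, counts)

    # stage 5: dominant-model family filter ---------------------------------
    retained, flagged = stage("dominant filter", lambda: dominant_shared_filter(
        survivors, genotypes, cases=cases, controls=controls,
        missing="strict"))
    report.add_stage("dominant model (shared by cases, absent in controls)",
                     {"shared": len(retained)})
    report.check_monotone()

    # stage 6: co-segregation in unaffected relatives -----------------------
    passing, failing = stage("co-segregation", lambda: cosegregation_check(
        retained, bundle.relative_genotypes, bundle.pedigree))

    # stage 7: prioritization -----------------------------------------------
    def run_rank():
        scored, panel_occ, ref_occ = [], {}, {}
        for key in passing:
            ann, profile = bundle.annotations[key]
            scored.append(consensus_score(
                key, ann.gene, profile,
                gerp_conserved_threshold=gerp_conserved_threshold,
                conservation_bonus=conservation_bonus))
            gts = bundle.panel_genotypes.get(key, {})
            counts = fassoc.screen_panel(gts, bundle.panel_groups)
            panel_occ[key] = counts.control_carriers
            ref_occ[key] = sum(
                1 for db in ("EVS", "inhouse")
                if bundle.popdb.get(key, {}).get(db) is not None
                and bundle.popdb[key][db].present)
        return rank_candidates(scored, panel_occ, ref_occ)

    ranked = stage("prioritization", run_rank)

    # stage 8: case-control association -------------------------------------
    def run_assoc():
        panel_counts, results = {}, {}
        for key in passing:
            gts = bundle.panel_genotypes.get(key)
            if not gts:
                continue
            counts = fassoc.screen_panel(gts, bundle.panel_groups)
            extra_alt = extra_total = extra_carriers = 0
            if include_family_cases:
                for s in cases:
                    zyg = genotypes.get(key, {}).get(s, "missing")
                    if zyg == "missing":
                        continue
                    extra_alt += {"hom_ref": 0, "het": 1, "hom_alt": 2}[zyg]
                    extra_total += 2
                    extra_carriers += int(zyg != "hom_ref")
            counts = fassoc.PanelCounts(
                case_carriers=counts.case_carriers + extra_carriers,
                control_carriers=counts.control_carriers,
                case_alt_alleles=counts.case_alt_alleles + extra_alt,
                case_total_alleles=counts.case_total_alleles + extra_total,
                control_alt_alleles=counts.control_alt_alleles,
                control_total_alleles=counts.control_total_alleles,
                n_missing=counts.n_missing)
            panel_counts[key] = counts
            if counts.degenerate:
                results[key] = fassoc.AssocResult(
                    None, 1, None, None, reason="empty panel arm")
            else:
                results[key] = fassoc.allelic_chisq(counts.allele_table())
        return panel_counts, results

    panel_counts, assoc_results = stage("association", run_assoc)

    log = {
        "thresholds": thresholds.as_dict(),
        "db_order": list(db_order),
        "gerp_conserved_threshold": gerp_conserved_threshold,
        "conservation_bonus": conservation_bonus,
        "include_family_cases": include_family_cases,
        "n_input_records": len(bundle.records),
        "n_off_target_dropped": n_off,
        "n_dominant_retained": len(retained),
        "n_flagged_missing": len(flagged),
        "n_candidates": len(passing),
    }
    result = PipelineResult(report=report, candidates=passing,
                            coseg_failures=failing, ranked=ranked,
                            panel_counts=panel_counts,
                            assoc_results=assoc_results, log=log)
    if out_dir is not None:
        result.write(out_dir)
    return result
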