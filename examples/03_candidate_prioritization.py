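"""Score and rank the packaged 22-candidate table.

Each candidate gets a predictor-consensus score (fraction of available
SIFT / MutationTaster / PolyPhen-2 / PMut calls voting damaging, plus a
conservation bonus when GERP >= 4), then the list is ordered with
healthy-control-panel-negative variants first.
"""

from famvar import consensus_score, rank_candidates
from famvar.io import candidate_table_path, read_annotation_table

table = read_annotation_table(candidate_table_path())

# genes observed at least once in the 401-member healthy control panel
panel_positive = {"THBS1", "SYNE1", "CHD8", "TMEM240", "AKAP1", "COX4I2",
                  "ZNF655", "KCNV2"}

scored = [consensus_score(key, ann.gene, profile)
          for key, (ann, profile) in table.items()]
ranked = rank_candidates(scored, {g: 1 for g in panel_positive})

print(f"{'rank':>4} {'gene':10} {'votes':>7} {'GERP':>6} "
      f"{'score':>6} panel")
for i, rec in enumerate(ranked, 1):
    votes = f"{rec.damaging_votes}/{rec.votes_available}"
    score = "--" if rec.score is None else f"{rec.score:.2f}"
    seen = "HC+" if rec.gene in panel_positive else "-"
    print(f"{i:>4} {rec.gene:10} {votes:>7} {rec.gerp:>6.2f} "
          f"{score:>6} {seen}")
# Panel-negative candidates outrank panel-positive ones regardless of
# score; within each block the predictor vote fraction plus the GERP
# conservation bonus decides, with the gene symbol as the final tiebreak.
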