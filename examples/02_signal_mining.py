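"""Full signal-mining pass: clean, stratify, flag, and summarize.

Simulates a cohort with planted duplicates and two planted signal terms,
assembles the analysis-ready dataset (deduplication, demographic
normalization, exposure definition), and prints the flagged signals with
their ROR/PRR intervals plus a publication-style cohort summary.
"""

import faerskit as fk
from faerskit import faers_io, signals
from faerskit.meddra import PtSocMap

vocab = list(fk.synthetic.default_vocabulary())
vocab[0] = fk.TermSpec(vocab[0].pt_name, vocab[0].soc_name, 0.01, 4.0)
vocab[5] = fk.TermSpec(vocab[5].pt_name, vocab[5].soc_name, 0.005, 3.0)

cfg = fk.SimConfig(n_reports=80_000, duplicate_rate=0.05, vocabulary=tuple(vocab), seed=11)
tables, truth = fk.simulate_reports(cfg)
print(f"raw DEMO rows: {len(tables.demo):,} (includes planted duplicate versions)")

ds = faers_io.assemble_dataset(
    tables.demo, tables.drug, tables.reac, tables.ther, tables.outc,
    synonyms={"baricitinib"},
)
print(f"deduplicated cases: {ds.n_cases:,}  exposed: {len(ds.exposed):,}")

soc_map = PtSocMap.from_pairs([(t.pt_name, t.soc_name) for t in cfg.vocabulary])
rows = signals.run_disproportionality(ds, level="PT", soc_map=soc_map)
print("\nflagged signals (a >= 3, ROR and PRR CI lower limits > 1):")
for r in rows:
    if r.is_signal:
        print(
            f"  {r.term}: a={r.table.a}, "
            f"ROR {r.ror.point:.2f} ({r.ror.ci_low:.2f}, {r.ror.ci_high:.2f}), "
            f"PRR {r.prr.point:.2f} ({r.prr.ci_low:.2f}, {r.prr.ci_high:.2f})"
        )
print(f"planted signal terms were: {truth.signal_terms}")

summary = signals.summarize_demographics(ds.subset(ds.exposed))
print("\nexposed-cohort gender mix (count, percent):")
for cat, count, pct in summary.blocks["gender"]:
    print(f"  {cat}: {count} ({pct:.2f})")
print(
    f"weight median (IQR): {summary.weight_median:.2f} "
    f"({summary.weight_q1:.2f}, {summary.weight_q3:.2f}) kg"
)
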