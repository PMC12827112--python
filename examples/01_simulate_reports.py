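"""Generate a synthetic spontaneous-report cohort with a planted signal.

Builds a small vocabulary in which one event term is reported three times
more often among drug-exposed cases, simulates 50,000 case reports, and
compares the estimated reporting odds ratio against the closed-form truth.
"""

import faerskit as fk
from faerskit import faers_io
from faerskit.signals import ContingencyTable, ror_estimate

vocabulary = (
    fk.TermSpec("RASH", "Skin disorders", background_prob=0.01, signal_multiplier=3.0),
    fk.TermSpec("NAUSEA", "Gastrointestinal disorders", background_prob=0.02),
    fk.TermSpec("HEADACHE", "Nervous system disorders", background_prob=0.015),
)
cfg = fk.SimConfig(n_reports=50_000, p_exposed=0.05, vocabulary=vocabulary, seed=7)
tables, truth = fk.simulate_reports(cfg)

print(f"reports: {len(tables.demo):,}  reactions: {len(tables.reac):,}")
print(f"true odds ratio for RASH: {truth.true_or['RASH']:.4f}")

exposed = faers_io.find_exposed_cases(tables.drug, {"baricitinib"})
with_event = set(tables.reac.loc[tables.reac["pt"] == "RASH", "caseid"])
a = len(with_event & exposed)
c = len(with_event) - a
t = ContingencyTable(a, len(exposed) - a, c, len(tables.demo) - len(exposed) - c)
est = ror_estimate(t)
print(f"estimated ROR: {est.point:.2f}  95% CI ({est.ci_low:.2f}, {est.ci_high:.2f})")
# The interval should cover the generative truth printed above: the planted
# three-fold reporting multiplier is recovered from the raw tables alone.
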