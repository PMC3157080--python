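"""Evaluate classifier performance and re-express it at another prevalence.

Scores a 500-patient synthetic cohort by leave-one-out prediction, then
summarises clinical performance: sensitivity/specificity of the high-risk
call, ROC AUC, per-tier relative risks with 95% CIs, and PPV/NPV converted
by Bayes' rule to the 23% baseline prevalence and to the 39% prevalence of
a T3-restricted testing population.
"""

from nodalrisk import (
    ReferenceCohort,
    SimulationConfig,
    evaluate,
    generate_cohort,
    ppv_npv_at_prevalence,
    predict_cohort,
)

matrix, labels = generate_cohort(
    SimulationConfig(n_samples=500, effect_size=1.0, seed=20)
)
cohort = ReferenceCohort(matrix=matrix, labels=labels)
predictions = predict_cohort(matrix, cohort, leave_one_out=True)

report = evaluate(predictions, labels.to_numpy(), prevalence_override=0.23)
c = report.confusion
print(f"confusion: tp={c.tp} fp={c.fp} tn={c.tn} fn={c.fn}")
print(f"sensitivity={c.sensitivity:.3f} specificity={c.specificity:.3f}")
print(f"PPV={report.ppv:.3f} NPV={report.npv:.3f} (at 23% prevalence)")
print(f"AUC={report.auc:.3f}")
for g in report.group_risks:
    if g.defined:
        print(f"RR[{g.group:12s}] = {g.rr:5.2f}  (95% CI {g.ci_low:.2f}-{g.ci_high:.2f})"
              f"  [{g.events_in}/{g.n_in} vs {g.events_out}/{g.n_out}]")

# the same test applied only to T3 tumors (39% prevalence of nodal disease)
ppv39, npv39 = ppv_npv_at_prevalence(c.sensitivity, c.specificity, 0.39)
print(f"at 39% prevalence (T3 only): PPV={ppv39:.3f} NPV={npv39:.3f}")
# Sensitivity/specificity are properties of the test; PPV/NPV depend on the
# population. Restricting testing to higher-stage disease raises PPV at the
# cost of NPV.
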