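"""Generate a synthetic landscape and run the full assessment on it.

Two states, 30% priority coverage, 2,000 parcels acquired under the mixture
process with influence 0.6 (easements 0.44, fee simple 0.78).  The pipeline
clips everything to the state boundaries, stratifies by date and tenure,
dissolves each stratum, intersects with the priorities, and reports areas,
scores, and the centroid chi-square test.
"""

from prioralign import SimulationConfig, run_assessment, simulate

cfg = SimulationConfig(n_states=2, state_size=800.0, coverage=0.3, n_parcels=2000, seed=11)
landscape = simulate(cfg)
report = run_assessment(landscape.lands, landscape.priorities, landscape.states)

print(f"{'stratum':<12}{'km2':>12}{'P_TNC':>9}{'score':>9}")
for label, s in report.strata.items():
    p = "   --" if s.p_tnc is None else f"{100 * s.p_tnc:6.1f}%"
    sc = "   --" if s.score is None else f"{100 * s.score:6.1f}%"
    print(f"{label:<12}{s.a_tnc:>12.1f}{p:>9}{sc:>9}")

print("\nper state (all records):")
for name, s in sorted(report.by_state.items()):
    print(
        f"  {name}: {s.a_tnc:9.1f} km2 acquired, "
        f"P_TNC {100 * s.p_tnc:5.1f}%, P_S {100 * s.p_s:5.1f}%, "
        f"score {100 * s.score:5.1f}%"
    )

t = report.centroid_test
print(
    f"\ncentroid test: {t.n_in} of {t.n_total} record centroids inside priorities"
    f"\n  expected {t.expected_in:.0f} under the {100 * t.p_null:.1f}% coverage null"
    f"\n  chi2 = {t.chi2:.1f} (1 df), p = {t.p_value:.3g}"
)
print(
    "\nThe all-records score should sit near the configured mixture of"
    "\ninfluence parameters; the chi-square rejects the no-influence null."
)
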