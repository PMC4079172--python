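"""Calibration sensitivity: one borderline study, rerun end to end.

Pugh (2002) sits on the 'moderately to highly effective' boundary and
could defensibly be calibrated 0.666 (more in) or 0.333 (more out).  The
analysis is run both ways; because the alternative turns the (1,1) row
into a genuine 3-vs-1 disagreement, majority vote-count resolution keeps
the row in play for minimisation.
"""

from qcakit import RunConfig, load_fixture, sensitivity_recalibrate

config = RunConfig(conditions=("Intensity", "Quality"), strategy="vote_count")
result = sensitivity_recalibrate(config, "Pugh (2002)", 0.333, table=load_fixture())

print(f"outcome membership: {result.original_outcome:.3f} -> {result.alternative_outcome:.3f}")
print(f"solution (base):    {result.base.solution_label}")
print(f"solution (altered): {result.altered.solution_label}")
print(
    f"coverage:    {result.base.metrics.solution_coverage:.3f} -> "
    f"{result.altered.metrics.solution_coverage:.3f}"
)
print(
    f"consistency: {result.base.metrics.solution_consistency:.3f} -> "
    f"{result.altered.metrics.solution_consistency:.3f}"
)
print("\nper-row consistency deltas (altered - base):")
for corner, delta in result.consistency_deltas().items():
    print(f"  {corner}: {'remainder' if delta is None else f'{delta:+.3f}'}")

# The solution expression survives the recalibration, but both coverage and
# consistency drop: the headline message holds while the support weakens.
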