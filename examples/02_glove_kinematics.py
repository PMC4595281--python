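"""Score a simulated data-glove run: movements, compliance, mirroring.

A subject follows the 1-second flexion-extension cue during 20 s movement
blocks.  The instructed hand's trace yields the movement count and the
compliance correlation (envelope vs task boxcar); the other hand's trace
yields MM_glove, the overt mirror-movement score.
"""

from hemiscope import GroundTruth, make_task_boxcar, score_glove_pair, simulate_glove_trace

boxcar = make_task_boxcar(block_s=20, total_s=360, dt=0.5)

for gain in (0.0, 0.5):
    truth = GroundTruth(mirror_gain=gain, seed=42)
    active, inactive = simulate_glove_trace(boxcar, truth)
    res = score_glove_pair(active, inactive, boxcar)
    print(f"mirror_gain={gain}: movements={res.n_movements}, "
          f"compliance r={res.compliance_r:.2f}, MM_glove={res.mirror_r:.2f}")

print("""
~90 movements per 6-minute task and compliance r around 0.7-0.9 match a
well-performing subject.  With no leakage (gain 0) the inactive hand is
uncorrelated with the task (|r| ~ 0); injected leakage drives MM_glove up.
""")
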