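"""Generate a small experimental session and show its stimuli.

Builds a 10-trial session in the low-disruption condition (p_r = 0.9,
p_d = 0.1): half the trials come from the fair-coin generator, half from
the disrupted-Markov (DMS) generator, in random order.  DMS rows tend to
show long monochromatic streaks; random rows alternate more.
"""

from patdet import build_session, seq_to_str

session = build_session("LD", n_trials=10, seed=0)
print(f"condition LD: p_r={session.params.p_r}, p_d={session.params.p_d}, "
      f"n={session.params.n}, seed={session.seed}")
for trial in session.trials:
    print(f"  trial {trial.index:2d}  {seq_to_str(trial.sequence)}  {trial.true_label}")
n_dms = sum(t.true_label == "DMS" for t in session.trials)
print(f"{n_dms} DMS and {session.n_trials - n_dms} random trials (exact balance).")
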