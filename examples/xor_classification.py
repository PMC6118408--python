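"""Solve the spiking exclusive-or with a hidden layer and random feedback.

Four jittered 10 ms input patterns built from a reference set and two
feature sets must be separated into two classes (label = parity of feature
presence — a task no network without hidden units can solve).  Patterns
arrive in random order over 4 Hz background firing; each readout must spike
inside a 25 ms response window after its class's stimuli only.
"""

from superspike import ExperimentConfig, run_xor_task

cfg = ExperimentConfig(
    task="xor", seed=1, n_hidden=8, n_output=2, n_presentations=1500,
    feedback_mode="random", r0=1e-3,
)
res = run_xor_task(cfg)
acc = res["correct"]
print(f"presentations: {acc.size}")
for lo in range(0, acc.size, 300):
    print(f"  accuracy over presentations {lo:4d}-{lo + 300:4d}: "
          f"{acc[lo:lo + 300].mean():.2f}")
print(f"consecutive correct responses at the end of training: {res['perfect_tail']} "
      "(correct readout spiked in-window, wrong readout silent)")
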