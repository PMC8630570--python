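"""Simulate one session of each task and summarise the behaviour.

The PRL agent learns stimulus values from probabilistic feedback (80/20
contingencies that reverse after 40 trials); the WCST agent reallocates
attention over card dimensions under deterministic rule feedback.
"""

import setshift as ss

# A reasonably exploitative learner: quick learning from both feedback
# valences, strong value-driven choice, mild tendency to repeat itself.
prl_params = ss.PRLParams(alpha_rew=0.4, alpha_pun=0.4, beta=6.0, kappa=0.5)
prl_trials = ss.prl_simulate(prl_params, ss.PRLConfig(), seed=1)
m = ss.prl_measures(prl_trials)
print("PRL session (80 trials):")
print(f"  accuracy  acquisition {m.p_correct['acquisition']:.2f}, reversal {m.p_correct['reversal']:.2f}")
print(f"  perseveration after reversal: {m.p_perseverative:.2f}")
print(f"  switch after spurious negative (reversal): {m.p_switch_after_spurious_negative['reversal']}")
# Healthy-adult-like behaviour shows high accuracy in both phases and a
# short perseverative run right after the contingencies flip.

wcst_params = ss.WCSTParams(r=0.6, p=0.6, d=3.0)
wcst_trials = ss.wcst_simulate(wcst_params, ss.WCSTConfig(), seed=1)
w = ss.wcst_measures(wcst_trials)
print("\nWCST session:")
print(f"  trials played: {len(wcst_trials)}, sets completed: {w.sets_completed}/9")
print(f"  error proportions: perseverative {w.p_perseverative_errors:.3f}, "
      f"nonperseverative {w.p_nonperseverative_errors:.3f}, unique {w.p_unique_errors:.3f}")
print(f"  trials to first set: {w.trials_to_first_set}")
# A learner with high consistency completes most of the 9 sets; its errors
# cluster right after rule changes (perseverative category).
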