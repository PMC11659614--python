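"""Estimate intrinsic neural timescales from a known ground truth.

Generates an Ornstein-Uhlenbeck signal whose autocorrelation decays with a
known constant, then recovers tau (exponential ACF fit) and ACW-0 (first
zero crossing of the ACF) from non-overlapping 10-s windows.
"""

import numpy as np

from intflex.containers import Recording
from intflex.synthetic import OUSpec, gen_ou_series
from intflex.timescales import windowed_int

TAU_TRUE = 0.3  # seconds

spec = OUSpec(tau_true=TAU_TRUE, sigma=1.0, fs=20.0, duration=600.0, seed=1)
rec = Recording(gen_ou_series(spec), fs=spec.fs)
table = windowed_int(rec, window_s=10.0)
conv = table[table["converged"]]

print(f"ground-truth tau: {TAU_TRUE:.3f} s")
print(f"windows estimated: {table['window'].nunique()}, "
      f"converged: {len(conv)}")
print(f"median tau estimate: {conv['tau_s'].median():.3f} s")
print(f"median ACW-0:        {conv['acw0_s'].median():.3f} s")
print()
print("The median windowed tau should sit near the ground truth (short")
print("windows bias it slightly low); ACW-0 tracks the same decay on a")
print("different scale (the zero crossing, not the 1/e point).")
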