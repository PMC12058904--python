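"""Watch P(normal) climb toward 1 as the leaf count grows.

Uniform decorated trees are sampled at fixed k = 2 over an increasing
grid of n; the fraction whose graph is a normal network rises with n,
the finite-size face of the limit P(normal) -> 1.  The bracketed ranges
are 95% Wilson score intervals.
"""

from arcnets import trend_experiment

rows = trend_experiment(k=2, n_grid=[5, 10, 20, 40, 80], samples=4000, seed=1)
print("  n   P(normal)   95% interval        P(temporal | normal)")
for r in rows:
    lo, hi = r.normal_interval
    hyb = r.hyb_given_normal
    print(f"{r.n:>4}   {r.p_normal:.3f}      [{lo:.3f}, {hi:.3f}]"
          f"      {hyb if hyb is None else round(hyb, 3)}")
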