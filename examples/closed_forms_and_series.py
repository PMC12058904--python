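"""Closed-form counts, generating functions, and asymptotics.

Prints the exact numbers of hybridization networks with one and two
reticulations for small n, shows that the generating-function expansion
reproduces them, and compares the exact counts with the asymptotic
prediction 2^(k-1) sqrt(2)/k! (2/e)^n n^(n+2k-1).
"""

import math

from arcnets import (H1_exact, H2_exact, N2_exact, N_asym, H1_series,
                     H2_series, egf_coeff)
from arcnets.formulas import log_ratio

print("n    H_{n,1}      H_{n,2}      N_{n,2}")
for n in range(4, 9):
    print(f"{n}  {H1_exact(n):>9}  {H2_exact(n):>11}  {N2_exact(n):>11}")

h1, h2 = H1_series(8), H2_series(8, form="partial_fractions")
print("\nseries check: n![z^n]H_1 at n=4 ->", egf_coeff(h1, 4),
      "; n![z^n]H_2 at n=6 ->", egf_coeff(h2, 6))

# the exact/asymptotic ratio drifts toward 1 as n grows (k = 2 here)
print("\nn    N2_exact / prediction")
for n in (25, 50, 100, 200):
    print(f"{n:>3}  {math.exp(log_ratio(N2_exact(n), N_asym(n, 2))):.4f}")
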