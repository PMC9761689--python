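"""The two-center re-expansion at work, including radii beyond the partner.

A single exterior screened harmonic (l, m) = (2, 1) centered 3.1 scaled
units up the z axis is re-expanded about the origin and compared with
direct evaluation -- at radii both below and ABOVE the center distance,
the regime classical expansions cannot reach.
"""

import numpy as np

from debyepair.special import kn_table, legendre_table
from debyepair.translation import TranslationTable, translate_exterior

R = 3.1  # scaled center distance
n_max = 52
table = TranslationTable(n_max, R, direction=+1, m_list=[1])
G = np.zeros((n_max + 1, n_max + 1))
H = np.zeros_like(G)
G[2, 1] = 1.0

rng = np.random.default_rng(7)
r = np.array([0.6, 1.4, 2.0, 4.7, 5.8])  # last two: r > R
th = rng.uniform(0.3, 2.8, r.size)
ph = rng.uniform(0.0, 2 * np.pi, r.size)

val, dval, ok = translate_exterior((G, H), r, th, ph, table)
x = r * np.sin(th) * np.cos(ph)
y = r * np.sin(th) * np.sin(ph)
z = r * np.cos(th)
rj = np.sqrt(x**2 + y**2 + (z - R) ** 2)
muj = (z - R) / rj
direct = kn_table(2, rj)[2] * legendre_table(2, 1, muj)[1] * np.cos(np.arctan2(y, x))

print(" r/R    re-expansion     direct eval     rel. err")
for k in range(r.size):
    rel = abs(val[k] - direct[k]) / abs(direct[k])
    print(f"{r[k]/R:5.2f}  {val[k]:14.6e} {direct[k]:14.6e}  {rel:9.2e}")
print()
print("Rows with r/R > 1 exercise the exterior regime of the re-expansion;")
print("agreement near machine precision away from the crossing sphere r = R\n(where convergence slows to the geometric rate (r/R)^n) shows the\ntranslation is exact up to")
print("series truncation.")
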