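"""The same machinery applied to classical (second-order) DTI.

For the 6-coefficient Gaussian model the K-optimal design-matrix
condition number is sqrt(7)/2 ~= 1.3229 for any N >= 6, and a minimal
6-direction scheme realizing it is recovered by point extraction.  A
second-order tensor D also embeds exactly into the order-4 model via
g'Dg = (g'Dg)(g'g), which the last lines demonstrate.
"""

import numpy as np

from koges import (
    ExtractionConfig,
    adc,
    embed_second_order,
    extract_points,
    solve_koptimal,
)

sdp = solve_koptimal(order=2, N=6)
print(f"kappa(G)* for DTI      : {sdp.kappa_G_star:.4f}  (sqrt(7)/2 = {np.sqrt(7)/2:.4f})")

res = extract_points(sdp.q_star, ExtractionConfig(N=6, order=2, seed=0))
print(f"extracted 6 directions : kappa(G) = {res.kappa_G:.4f}")
print(res.directions.points.round(4))

# embedding a Gaussian profile into the order-4 model preserves the ADC
D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])  # a prolate tensor, mm^2/s
t4 = embed_second_order(D)
g = np.array([0.6, 0.8, 0.0])
print(f"g'Dg = {g @ D @ g:.6e},  order-4 ADC = {adc(t4, g):.6e}")
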