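"""Recover planted cross-regional co-activation motifs with the Barcode method.

Plants two known co-activation patterns (OB+aPC gamma; OB+LEC theta) into a
3-region recording, runs masked EMD -> amplitude channels -> 250-ms
co-participation features -> ICA, and matches the fitted barcodes to the
planted signatures by cosine similarity.  Also scores how well each matched
barcode's strength separates activation from baseline epochs (ROC-AUC).
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from oscibar.barcode import barcode_score, fit_barcode_pipeline
from oscibar.core import BETA, GAMMA, THETA, EventTable
from oscibar.simulate import BarcodePattern, OscSpec, plant_barcode_patterns, simulate_lfp

rng = np.random.default_rng(5)


def random_blocks():
    """Independent 5-s activation blocks (~40% of the recording)."""
    act = rng.uniform(size=48) < 0.4
    on = [(i * 5.0, (i + 1) * 5.0) for i in np.nonzero(act)[0]]
    off = [(i * 5.0, (i + 1) * 5.0) for i in np.nonzero(~act)[0]]
    return on, off


(on_g, off_g), (on_t, off_t) = random_blocks(), random_blocks()
patterns = [
    BarcodePattern("gamma-motif", {("OB", "gamma"): 1.0, ("aPC", "gamma"): 1.0}, on_g),
    BarcodePattern("theta-motif", {("OB", "theta"): 1.0, ("LEC", "theta"): 1.0}, on_t),
]
oscs = [
    OscSpec(r, b, f, a, phase_diffusion=d)
    for r in ["OB", "aPC", "LEC"]
    for b, f, d, a in [(THETA, 8.0, 4.0, 60.0), (BETA, 25.0, 12.0, 25.0),
                       (GAMMA, 60.0, 40.0, 20.0)]
]
rec = simulate_lfp(oscs, {"alpha": 1.0, "sigma": 15.0}, 240.0, 1000.0, 5,
                   regions=["OB", "aPC", "LEC"])
rec, truths = plant_barcode_patterns(rec, patterns, 6)

model, strengths, _ = fit_barcode_pipeline(rec, n_barcodes=6, seed=0)
S = np.stack([t.signature for t in truths])
C = np.abs(S @ model.W.T)
ri, ci = linear_sum_assignment(-C)

baselines = {"gamma-motif": off_g, "theta-motif": off_t}
for k in range(len(truths)):
    t, c = truths[ri[k]], ci[k]
    rest = baselines[t.name]
    rows = [dict(epoch_id=f"a{i}", label="x", start_s=s, end_s=e, condition="novel")
            for i, (s, e) in enumerate(t.epochs)]
    rows += [dict(epoch_id=f"b{i}", label="x", start_s=s, end_s=e, condition="familiar")
             for i, (s, e) in enumerate(rest)]
    score = barcode_score(strengths[c], EventTable.from_rows(rows), "novel", "familiar")
    print(f"{t.name:12s} -> barcode #{c}: cosine {C[ri[k], c]:.3f}, "
          f"activation ROC score {score:.3f}")

print("\ncosine compares the fitted barcode (ICA component pattern over")
print("region-band co-participation features) with the planted signature;")
print("the ROC score asks whether barcode strength identifies when the")
print("motif was active (0.5 = chance, 1 = perfect).")
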