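"""Theta-gamma coupling and spike-phase locking on simulated OB activity.

Measures the Tort modulation index (theta phase -> gamma amplitude) and
each unit's mean resultant length (MRL) with the Rayleigh test, for one
control and one lesion subject.  The lesion subject halves its PAC and
loses gamma locking while theta locking is spared.
"""

from oscibar.core import GAMMA, THETA
from oscibar.coupling import bandpass_analytic, classify_locked, pac_mi, spike_phase_locking
from oscibar.simulate import CohortSpec, simulate_cohort

subjects, _ = simulate_cohort(CohortSpec(n_per_group=1, duration_s=120.0, rng_seed=3))

for rec, _events in subjects:
    x = rec.region_signal("OB")
    mi = pac_mi(
        bandpass_analytic(x, rec.fs_hz, THETA),
        bandpass_analytic(x, rec.fs_hz, GAMMA),
    ).mi
    print(f"\n=== {rec.subject_id} ({rec.group}): theta->gamma MI = {mi:.4f} ===")
    for u in rec.units[:4]:
        for band in (THETA, GAMMA):
            res = spike_phase_locking(u, x, rec.fs_hz, band)
            locked = "locked" if classify_locked(res) else "not locked"
            print(f"  {u.unit_id} {band.name:5s}: MRL {res.mrl:.3f} "
                  f"(p = {res.rayleigh_p:.2e}, {locked})")

print("\nMI is the normalized KL divergence of the phase-binned gamma")
print("amplitude profile (0 = no coupling).  MRL is the resultant of spike")
print("phases (0 = uniform, 1 = perfectly locked); a unit is phase-locked")
print("when the Rayleigh test rejects uniformity at alpha = 0.05.")
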