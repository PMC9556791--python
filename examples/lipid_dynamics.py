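"""Lipid motional correlation times from 31P relaxation.

Generates paired sample/control T1 and T2 decay series from the full
two-timescale rate model (a peptide-bound membrane with restricted
headgroup motion vs. a peptide-free control), fits the exponentials,
inverts them to the fast/slow correlation times, and reports the
peptide-induced changes.
"""

import memfibril as mf
from memfibril.synthetic import gen_relaxation_set

# ground truth: peptide addition slows headgroup motion (tau_f up 0.3 ns)
# and speeds lateral diffusion (tau_s down 0.5 us)
sets = gen_relaxation_set(
    tau_f=1.8e-9,
    tau_s=4.0e-6,
    control_tau_f=1.5e-9,
    control_tau_s=4.5e-6,
    noise_sd=0.02,
    seed=42,
)

results = {}
for role in ("sample", "control"):
    t1_fit = mf.fit_exponential_decay(sets[f"{role}_T1"])
    t2_fit = mf.fit_exponential_decay(sets[f"{role}_T2"])
    res = mf.invert_simplified(t1_fit, t2_fit, label=role)
    results[role] = res
    print(
        f"{role:8s}  T1 = {t1_fit.tau:.3f} s  T2 = {t2_fit.tau*1e3:.2f} ms  "
        f"tau_f = {res.tau_f*1e9:.2f} +/- {res.sigma_tau_f*1e9:.2f} ns  "
        f"tau_s = {res.tau_s*1e6:.2f} +/- {res.sigma_tau_s*1e6:.2f} us  "
        f"(w*tau_f)^2 = {res.validity_metric:.1f} valid={res.valid}"
    )

delta = mf.delta_correlation_times(results["sample"], results["control"], "5 h")
print(
    f"\nDelta tau_f = {delta.delta_tau_f*1e9:+.2f} +/- {delta.sigma_delta_f*1e9:.2f} ns"
    f"  (positive: headgroup motion restricted by the peptide)"
)
print(
    f"Delta tau_s = {delta.delta_tau_s*1e6:+.2f} +/- {delta.sigma_delta_s*1e6:.2f} us"
    f"  (negative: lateral diffusion accelerated)"
)
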