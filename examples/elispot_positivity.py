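"""Call ELISPOT responses with the distribution-free resampling test.

Simulates negative-binomial replicate plates with and without a true
antigen effect, runs the exact permutation (DFR) test, and applies the
significant / DR / NS calling rule.
"""

from immunotrack import classify_response, dfr_test, gen_elispot

# a clear response: exhaustive enumeration over all C(6,3)=20 relabelings
p = dfr_test([40, 42, 38], [5, 6, 4])
print(f"clear response p-value: {p:.4f}")

for label, effect in (("no effect", 0.0), ("strong effect", 120.0)):
    assay = gen_elispot(mu_control=20.0, effect=effect, dispersion=10.0, seed=5)
    call = classify_response(assay)
    print(
        f"{label:>14}: antigen {assay.antigen_wells} vs control "
        f"{assay.control_wells} -> {call.call} "
        f"(p={call.p_value:.3f}, magnitude={call.magnitude:.1f})"
    )
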