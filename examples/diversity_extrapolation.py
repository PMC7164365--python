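"""Chao1 richness and the two-step global diversity extrapolation.

A densely sampled reference region (the Indo-Pacific for terebrids)
anchors the estimate: Chao1 extrapolates its richness from singleton and
doubleton counts, the Chao1/observed ratio measures sampling
effectiveness, and that ratio scales the worldwide count of described
species before newly delimited species are added.  State-specific
sampling fractions for diversification models follow the same logic per
trait state.
"""

from terebra import (DiversitySample, chao1, estimate_total_diversity,
                     state_sampling_fractions)

ip = DiversitySample(s_obs=143, f1=24, f2=11, region="Indo-Pacific")
c = chao1(ip)
print(f"Observed Indo-Pacific richness: {ip.s_obs}")
print(f"Chao1 estimate: {c.estimate:.1f} (f1={ip.f1}, f2={ip.f2})")

report = estimate_total_diversity(ip, worms_described=407,
                                  newly_delimited=69)
print(f"Sampling-effectiveness ratio: {report['ratio']:.3f}")
print(f"Estimated total richness: {report['total']:.0f} species")
# The ratio >1 says the region still hides unseen species; the total is
# the described world fauna scaled by that ratio plus new delimitations.

f0, f1 = state_sampling_fractions(
    ip_state_counts=(60, 40), total_diversity=report["total"],
    sampled_counts=(90, 40))
print(f"State-specific sampling fractions: f0={f0:.2f}, f1={f1:.2f}")
# These feed the state-dependent diversification likelihood, which must
# know how incompletely each character state was sampled.
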