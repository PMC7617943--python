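"""Closed-form predictions of the two attenuation models.

Computes the mean/SD/skewness of direct-condition matching forces implied
by subtractive and divisive attenuation at the Study-1-scale parameters
(attenuation factor 1.61 +/- 0.152, indirect force 2.0 +/- 0.3 N), the
skew-normal approximation to the divisive product distribution, and the
implied attenuation fraction.
"""

import forcematch as fm

att = fm.AttenuationParams(mean_K=1.61, sd_K=0.152)
ind = fm.IndirectLevelParams(target_force=2.0, mean_FI=2.0, sd_FI=0.3)

sub = fm.subtractive_moments(att, ind)
div = fm.divisive_moments(att, ind)
print(f"subtractive: mean {sub.mean:.3f} N, sd {sub.sd:.3f} N, skew {sub.skew:.3f}")
print(f"divisive:    mean {div.mean:.3f} N, sd {div.sd:.3f} N, skew {div.skew:.3f}")

sn = fm.skewnormal_from_moments(div)
print(
    f"skew-normal approximation: xi={sn.location:.4f}, omega={sn.scale:.4f}, "
    f"alpha={sn.shape:.4f}"
)

frac = fm.attenuation_fraction(att.mean_K)
sd_frac = fm.attenuation_fraction_sd(att.mean_K, att.sd_K)
print(
    f"attenuation fraction 1 - 1/{att.mean_K} = {frac:.2f} "
    f"(+/- {100 * sd_frac:.0f}%)"
)
# A divisive factor of 1.61 means the self-generated force feels 38% weaker;
# its trial-to-trial SD of 0.152 translates to about +/-6% around that.
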