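"""Scan a sequence for PWM binding sites at calibrated significance.

Site p-values are exact tail probabilities of the log-odds score under the
background model, computed by dynamic programming; a site is called when
its p-value is at most alpha = 0.005.
"""

import numpy as np

from dsxtargets import BackgroundModel, scan, score_distribution, threshold_for_alpha
from dsxtargets.simulate import default_pwm

pwm = default_pwm()
bg = BackgroundModel((0.3, 0.2, 0.2, 0.3))

dist = score_distribution(pwm, bg)
thr = threshold_for_alpha(pwm, bg, alpha=0.005, dist=dist)
print(f"motif: {pwm.name}, length {pwm.length}, consensus {pwm.consensus}")
print(f"information content: {pwm.information_content(bg):.2f} bits")
print(f"alpha=0.005 score threshold: {dist.to_bits(thr):.3f} bits "
      f"(attained tail {dist.tail(thr):.2e})")

# plant the consensus in random background and recover it
rng = np.random.default_rng(0)
seq = "".join(np.array(list("ACGT"))[rng.choice(4, 30_000, p=[.3, .2, .2, .3])])
seq = seq[:10_000] + pwm.consensus + seq[10_000:]
sites = scan({"chr1": seq}, pwm, bg, alpha=0.005)
print(f"\n{len(sites)} significant sites on 30 kb "
      f"(expected ~{2 * 30_000 * dist.tail(thr):.0f} by chance + 1 planted)")
planted = [s for s in sites if s.start == 10_000]
print(f"planted consensus recovered: {planted[0].start}-{planted[0].end} "
      f"strand {planted[0].strand}, score {planted[0].score:.2f} bits, "
      f"p = {planted[0].p_value:.2e}")
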