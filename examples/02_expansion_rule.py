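"""Classify hematoma expansion between baseline and follow-up CT.

Expansion means growth of more than 33% relative OR more than 12.5 mL
absolute — both strict, so values exactly on a threshold do not count.
"""

from hiikit import classify_expansion

cases = [
    (10.0, 13.4),   # +34% relative        -> expansion
    (10.0, 13.3),   # exactly +33%         -> no expansion (strict rule)
    (40.0, 52.6),   # +31.5% but +12.6 mL  -> expansion (absolute arm)
    (40.0, 52.5),   # both arms exactly on threshold -> no expansion
]
for baseline, followup in cases:
    verdict = classify_expansion(baseline, followup)
    growth = 100 * (followup - baseline) / baseline
    print(f"{baseline:5.1f} -> {followup:5.1f} mL  "
          f"(+{growth:4.1f}%, +{followup - baseline:4.1f} mL): {verdict}")
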