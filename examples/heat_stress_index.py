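"""Temperature-humidity index for barn climate readings.

THI = (1.8*T + 32) - (0.55 - 0.55*RH) * (1.8*T - 26), RH as a fraction.
THI < 72 is comfortable for dairy cattle; 72-78 mild, 78-89 moderate and
>= 90 severe heat stress.
"""

from spongenet import compute_thi

readings = [("winter barn", 5.0, 0.60), ("spring", 18.0, 0.55),
            ("summer morning", 28.0, 0.65), ("summer afternoon", 33.0, 0.70)]
for label, t, rh in readings:
    thi = compute_thi(t, rh)
    band = ("none" if thi < 72 else "mild" if thi < 78 else
            "moderate" if thi < 90 else "severe")
    print(f"{label:17s} T={t:4.1f} C  RH={rh:.0%}  THI={thi:5.1f}  stress: {band}")
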