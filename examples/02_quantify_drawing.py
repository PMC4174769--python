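"""Quantify single drawings: perfect, offset, and oscillating traces.

Shows the six drawing measures and the surrogate clinical score for three
synthetic pen trajectories with known geometry.
"""

from spiroquant import build_template, quantify
from spiroquant.pipeline import offset_trace, perfect_trace, sinusoid_trace

template = build_template(4, 56.0)


def show(name, m):
    print(
        f"{name:>9s}: length {m.length_cm:6.2f} cm | time {m.movement_time_s:5.1f} s | "
        f"speed {m.avg_speed:4.2f} cm/s | speed SD {m.speed_variability:5.3f} | "
        f"deviation {m.deviation_area:6.2f} cm^2 | crossings {m.crossings:2d} | score {m.clinical_score}"
    )


# An exact template trace: ~56 cm, no deviation, no crossings, score 0A.
show("perfect", quantify(perfect_trace(template), template))

# A trace drawn 0.3 cm outside the template everywhere: substantial
# deviation area (closed form A*b*Theta^2/2 + A^2*Theta/2 ~ 17.8 cm^2)
# but zero crossings, because it never passes through the template curve.
show("offset", quantify(offset_trace(template, offset=0.3), template))

# A trace weaving sinusoidally around the template (2 cycles per turn):
# every sine zero is a template crossing — 16 over the 4 turns.
show("sinusoid", quantify(sinusoid_trace(template), template))
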