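"""Relative growth rate between two fruit sampling points.

RGR = (ln w₂ − ln w₁) / (t₂ − t₁): log-scale mass gain per day, the
standard way to compare growth phases between varieties regardless of
absolute fruit size.
"""

from fruitfba import relative_growth_rate

# a fruit doubling its fresh weight over one week
rgr = relative_growth_rate(weight_1=10.0, weight_2=20.0, t1=0.0, t2=7.0)
print(f"doubling in 7 d: RGR = {rgr:.5f} per day")

# scale invariance: only relative mass gain matters
print(f"30 g → 60 g in 7 d: RGR = {relative_growth_rate(30, 60, 0, 7):.5f} per day")

# a slow late-season phase
print(f"80 g → 88 g over 10 d: RGR = {relative_growth_rate(80, 88, 100, 110):.5f} per day")
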