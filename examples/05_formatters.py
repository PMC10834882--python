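"""Attribute formatters: numbers to labels, strings/numbers to colours.

Formatters are declarative specs used by label and colour-aware plot
stages: round to significant or decimal digits, drop values outside a
threshold band, parse CSS colour strings, or map numbers onto a colour
gradient.
"""

from phylopipe import (Colour, FormatterSpec, format_number, gradient_map,
                       parse_css_colour, parse_number, Gradient)

sig = FormatterSpec(digits=3, digit_mode="significant")
dec = FormatterSpec(digits=2, digit_mode="decimal")
print("0.666666 ->", format_number(0.666666, sig), "(3 significant)")
print("1.235    ->", format_number(1.235, dec), "(2 decimals,"
      " half away from zero)")

banded = FormatterSpec(digits=2, max_threshold=1.5)
print("branch lengths 1.0 and 2.0 with max threshold 1.5 ->",
      [format_number(v, banded) for v in (1.0, 2.0)],
      "(None = label skipped)")

print('parse_number(" 1e-3 ") ->', parse_number(" 1e-3 "))

# The three equivalent CSS forms give one identical colour.
forms = ["red", "#FF0000", "rgb(255, 0, 0)"]
print({form: parse_css_colour(form).hex() for form in forms})

heat = Gradient(((0.0, Colour(0, 0, 255)), (1.0, Colour(255, 0, 0))))
print("support 0.75 on a blue-red gradient over [0.5, 1.0] ->",
      gradient_map(0.75, heat, (0.5, 1.0)).hex())
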