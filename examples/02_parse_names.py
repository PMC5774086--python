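"""Parse scientific names, name usages and concept labels.

A name usage may trail a status abbreviation; a concept label joins a
Linnaean name to its circumscribing reference with the keyword "sec.".
"""

from taxograph.names import (format_name, parse_concept_label,
                             parse_taxonomic_name_usage)

usage = parse_taxonomic_name_usage("Heser stoevi Deltschev 2016, sp. n.")
print("genus:", usage.name.genus, "| epithet:", usage.name.specific_epithet)
print("authorship:", usage.name.authorship, usage.name.year)
print("status:", usage.status.value, f"({usage.status_verbatim!r})")

label = parse_concept_label(
    "Andropogon virginicus var. tenuispatheus sec. Blomquist (1948)")
print("infraspecific:", label.name.infraspecific_marker,
      label.name.infraspecific_epithet)
print("sec. reference:", label.sec_reference)

roundtrip = format_name(parse_taxonomic_name_usage(
    "Harmonia manillana (Mulsant, 1866)").name)
print("formatted back:", roundtrip)

# Parsing is field-lossless: format(parse(s)) reproduces the printed form.
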