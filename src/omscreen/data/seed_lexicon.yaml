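# Seed screening lexicon for otitis media in free-text primary care notes.
#
# Surfaces confirmed in the running text of the source description: the full
# phrase 'otitis media', the tympanic-membrane variants 'T/M', 't/m', 'tm',
# 'TM' (listed as distinct case-sensitive terms), the ambiguous laterality
# abbreviation 'ROM', and the exclusion word 'normal'.  Standard laterality
# and acuity abbreviations (OM, AOM, LOM, BOM) complete the set.  Extend or
# correct this file per site; the content is data, not code.
version: seed-om-1
policy:
  mode: window
  window_tokens: 3
  bidirectional: true
search_terms:
  - surface: otitis media
    case_sensitive: false
    note: full diagnosis phrase
  - surface: OM
    case_sensitive: true
    note: otitis media abbreviation
  - surface: AOM
    case_sensitive: true
    note: acute otitis media
  - surface: ROM
    case_sensitive: true
    note: right otitis media (also 'range of movement' - known ambiguity)
  - surface: LOM
    case_sensitive: true
    note: left otitis media
  - surface: BOM
    case_sensitive: true
    note: bilateral otitis media
  - surface: T/M
    case_sensitive: true
    note: tympanic membrane variant
  - surface: t/m
    case_sensitive: true
    note: tympanic membrane variant
  - surface: tm
    case_sensitive: true
    note: tympanic membrane variant
  - surface: TM
    case_sensitive: true
    note: tympanic membrane variant
exclusion_words:
  - surface: normal
    case_sensitive: false
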