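# Seed keyword list hinting a citation should be EXCLUDED.
# Non-RCT publication types and non-human studies; edit freely
# (one phrase per line, '#' starts a comment).
case report
case series
review
systematic review
meta analysis
editorial
letter
comment
commentary
conference abstract
animal
animals
rat
rats
mouse
mice
rabbit
in vitro
cell line
cadaver
retrospective study
cross sectional
protocol
guideline
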