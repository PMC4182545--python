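pattern,tier
46 XX,universal
46 XY,universal
46-XX,universal
46-XY,universal
XO,universal
XX,universal
XY,universal
ambig,universal
chordee,universal
karyotyp,universal
penoscrotal,universal
perineal,universal
severe hypospad,universal
undescended,universal
CAH,extended
congenital adrenal hyperplasia,extended
gonad,extended
hypospad,extended
labia,extended
mosaic,extended
penile,extended
penis,extended
phall,extended
prader,extended
urogenital sinus,extended
viriliz,extended
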