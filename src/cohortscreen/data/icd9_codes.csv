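icd9_code,required_sex
255.2,F
259.5,
752,
752.4,
752.40,
752.49,
752.61,
752.64,
752.69,
752.7,
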