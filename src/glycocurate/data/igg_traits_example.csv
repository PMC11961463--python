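trait,formula
fucosylation,IgGI1H3N4F1 + IgGI1H4N4F1 + IgGI1H5N4F1 + IgGI1H3N5F1 + IgGI1H4N5F1 + IgGI1H5N4F1S1 + IgGI1H4N4F1S1
bisection,IgGI1H3N5F1 + IgGI1H4N5F1
galactosylation_per_antenna,0.5 * IgGI1H4N4F1 + 0.5 * IgGI1H4N4 + 0.5 * IgGI1H4N5F1 + 0.5 * IgGI1H4N4F1S1 + IgGI1H5N4F1 + IgGI1H5N4 + IgGI1H5N4F1S1
sialylation_per_antenna,0.5 * IgGI1H5N4F1S1 + 0.5 * IgGI1H4N4F1S1
fucosylation_of_diantennary,IgGI1H3N4F1 + IgGI1H4N4F1 + IgGI1H5N4F1 / IgGI1H3N4F1 + IgGI1H4N4F1 + IgGI1H5N4F1 + IgGI1H3N4 + IgGI1H4N4 + IgGI1H5N4
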