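plot_id,zone,x,y,area_ha
hyposaline,hyposaline,,,
mesosaline,mesosaline,,,
hypersaline,hypersaline,,,
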