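# Sulcus label vocabulary (free text; names follow the classical endocast atlases).
central
precentral
postcentral
superior frontal
middle frontal
inferior frontal
superior temporal
middle temporal
inferior temporal
sylvian
ascending ramus of sylvian
anterior horizontal ramus of sylvian
fronto-marginal
orbital
fronto-orbital
lateral calcarine
retro-calcarine
lateral occipital
transverse occipital
inferior occipital
lunate
intraparietal
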