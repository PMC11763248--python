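# Default anatomical target sets, resolved against the default HOA+AAL-style
# 132-parcel table. Region names listed here match the `name` column of the
# parcel table; a name matches every hemisphere it occurs in (left/right or
# midline), so bilateral structures contribute two parcels.
#
# MTL: medial temporal lobe atrophy target for the volume model.
# DMN: default-mode-network target for the connectome model. The full
# 31-parcel enumeration is a shipped default assembled from the commonly
# named core regions (medial prefrontal, posterior cingulate, precuneus,
# inferior parietal, lateral temporal, hippocampus, amygdala); edit freely.
target_sets:
  MTL:
    lateralized: true
    regions:
      - Hippocampus
      - Amygdala
      - Parahippocampal Gyrus anterior division
      - Parahippocampal Gyrus posterior division
  DMN:
    lateralized: true
    regions:
      - Frontal Medial Cortex
      - Paracingulate Gyrus
      - Subcallosal Cortex
      - Cingulate Gyrus anterior division
      - Cingulate Gyrus posterior division
      - Precuneous Cortex
      - Angular Gyrus
      - Supramarginal Gyrus anterior division
      - Supramarginal Gyrus posterior division
      - Middle Temporal Gyrus anterior division
      - Middle Temporal Gyrus posterior division
      - Middle Temporal Gyrus temporooccipital part
      - Superior Temporal Gyrus anterior division
      - Superior Temporal Gyrus posterior division
      - Temporal Pole
      - Hippocampus
      - Amygdala
      - Parahippocampal Gyrus anterior division
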