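dimension,level,decrement
mobility,1,0.0
mobility,2,0.10
mobility,3,0.30
self_care,1,0.0
self_care,2,0.10
self_care,3,0.30
usual_activities,1,0.0
usual_activities,2,0.10
usual_activities,3,0.30
pain_discomfort,1,0.0
pain_discomfort,2,0.10
pain_discomfort,3,0.30
anxiety_depression,1,0.0
anxiety_depression,2,0.10
anxiety_depression,3,0.30
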