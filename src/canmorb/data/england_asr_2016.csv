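cancer_type,gender,region,rate
all,male,North East,916.8
all,male,North West,888
all,male,Yorkshire and the Humber,852.1
all,male,East Midlands,821.1
all,male,West Midlands,812.5
all,male,East,807
all,male,London,807.5
all,male,South East,801.3
all,male,South West,836.1
all,female,North East,708.9
all,female,North West,700
all,female,Yorkshire and the Humber,680.9
all,female,East Midlands,672
all,female,West Midlands,648.4
all,female,East,658
all,female,London,622.9
all,female,South East,654
all,female,South West,687.9
lung,male,North East,250.5
lung,male,North West,232.3
lung,male,Yorkshire and the Humber,224.6
lung,male,East Midlands,188.2
lung,male,West Midlands,190.5
lung,male,East,170.6
lung,male,London,180
lung,male,South East,161.7
lung,male,South West,165.7
lung,female,North East,217.1
lung,female,North West,191.2
lung,female,Yorkshire and the Humber,179.7
lung,female,East Midlands,139.3
lung,female,West Midlands,130.7
lung,female,East,129
lung,female,London,140.3
lung,female,South East,124.3
lung,female,South West,124.1
bowel,male,North East,200.6
bowel,male,North West,193
bowel,male,Yorkshire and the Humber,182.9
bowel,male,East Midlands,181.6
bowel,male,West Midlands,186
bowel,male,East,176.4
bowel,male,London,161.7
bowel,male,South East,174.9
bowel,male,South West,181.1
bowel,female,North East,120.8
bowel,female,North West,124.3
bowel,female,Yorkshire and the Humber,117.5
bowel,female,East Midlands,120.7
bowel,female,West Midlands,119.6
bowel,female,East,127.2
bowel,female,London,115
bowel,female,South East,125.6
bowel,female,South West,129.2
prostate,male,North East,317.2
prostate,male,North West,342.9
prostate,male,Yorkshire and the Humber,345.2
prostate,male,East Midlands,344.1
prostate,male,West Midlands,363.2
prostate,male,East,379.2
prostate,male,London,372.9
prostate,male,South East,383
prostate,male,South West,392.8
breast,female,North East,199.7
breast,female,North West,203.8
breast,female,Yorkshire and the Humber,197.2
breast,female,East Midlands,207
breast,female,West Midlands,200.5
breast,female,East,203.9
breast,female,London,190.2
breast,female,South East,208.2
breast,female,South West,216.7
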