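sample_id,rf_tlc_analyzer,rf_imagej,content_tlc_analyzer,content_imagej,content_uv_vis,content_hplc
MT30,0.62,0.61,468.75,487.59,500.74,473.64
MT38,0.60,0.60,413.75,403.01,419.08,479.02
MT33,0.59,0.61,495.00,493.14,489.42,473.93
MT12,0.61,0.59,486.25,461.82,498.07,481.59
MT82,0.62,0.60,500.00,486.94,511.42,479.66
MT133,0.62,0.62,508.75,485.19,468.18,477.61
MT92,0.62,0.62,497.50,497.45,491.96,478.00
MT112,0.61,0.61,455.00,469.96,468.30,495.96
MT118,0.58,0.59,500.00,487.11,502.14,474.97
MT139,0.61,0.61,482.50,462.54,468.56,482.77
MT116,0.59,0.63,470.08,471.74,475.81,488.85
MT135,0.60,0.62,510.00,485.89,478.73,463.21
MT115,0.60,0.59,475.00,463.80,470.09,484.11
MT80,0.58,0.61,518.75,488.53,500.10,479.07
MT128,0.58,0.59,487.50,463.08,485.98,503.41
MT129,0.58,0.59,497.50,506.60,482.93,490.67
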