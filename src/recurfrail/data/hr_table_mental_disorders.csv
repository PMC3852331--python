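term,level,cfpm_hr,cfpm_lo,cfpm_hi,cpm_hr,cpm_lo,cpm_hi,fpm_hr,fpm_lo,fpm_hi,cm_hr,cm_lo,cm_hi,fm_hr,fm_lo,fm_hi,cfm_hr,cfm_lo,cfm_hi
sex,Female,0.91,0.88,0.93,0.93,0.91,0.95,0.9,0.88,0.92,0.93,0.92,0.95,0.89,0.87,0.92,0.92,0.9,0.94
age_group,29-35,0.84,0.81,0.87,0.86,0.84,0.89,0.84,0.81,0.87,0.88,0.86,0.9,0.82,0.79,0.86,0.85,0.82,0.88
age_group,36-45,0.76,0.73,0.78,0.81,0.78,0.83,0.76,0.73,0.78,0.82,0.8,0.84,0.73,0.71,0.76,0.78,0.75,0.8
age_group,>45,0.63,0.61,0.65,0.7,0.68,0.72,0.63,0.6,0.65,0.72,0.7,0.74,0.59,0.57,0.62,0.66,0.64,0.68
health_region,Lleida,1.05,0.98,1.12,1.05,1.0,1.11,1.04,0.97,1.12,1.04,1.0,1.09,1.04,0.97,1.12,1.05,0.98,1.11
health_region,Camp de Tarragona,1.09,1.04,1.15,1.03,0.98,1.07,1.1,1.05,1.16,1.04,1.0,1.08,1.16,1.09,1.23,1.07,1.02,1.12
health_region,Terres de l'Ebre,1.09,0.99,1.21,1.06,0.98,1.15,1.09,0.99,1.2,1.05,0.97,1.13,1.1,0.98,1.23,1.08,0.98,1.18
health_region,Girona,1.01,0.97,1.05,1.01,0.98,1.04,1.01,0.97,1.05,1.01,0.98,1.04,1.0,0.96,1.05,1.01,0.97,1.04
health_region,Catalunya Central,1.06,1.01,1.11,1.04,1.0,1.08,1.06,1.01,1.11,1.04,1.0,1.07,1.06,1.01,1.12,1.05,1.01,1.1
health_region,Alt Pirineu i Aran,0.99,0.79,1.25,0.95,0.78,1.16,0.99,0.78,1.25,0.94,0.79,1.13,1.01,0.78,1.31,0.97,0.79,1.19
activity_branch,"Manufacturing industry, energy production",1.04,0.71,1.52,0.99,0.72,1.35,1.05,0.72,1.55,1.01,0.76,1.32,1.09,0.71,1.67,1.03,0.73,1.45
activity_branch,Construction,1.02,0.7,1.49,0.99,0.72,1.36,1.02,0.69,1.5,1.01,0.76,1.33,1.05,0.68,1.51,1.01,0.72,1.43
activity_branch,Commercial/vehicles repair,0.89,0.61,1.3,0.88,0.64,1.2,0.89,0.61,1.31,0.91,0.69,1.19,0.91,0.59,1.39,0.89,0.64,1.26
activity_branch,"Hotel, restaurant businesses",0.88,0.6,1.29,0.87,0.63,1.19,0.88,0.6,1.3,0.9,0.68,1.18,0.9,0.58,1.38,0.89,0.63,1.25
activity_branch,Transportation/communication,0.91,0.62,1.34,0.9,0.66,1.24,0.92,0.63,1.36,0.93,0.7,1.22,0.94,0.61,1.44,0.92,0.65,1.3
activity_branch,"Finance, real estate, services",0.92,0.63,1.35,0.91,0.66,1.24,0.93,0.63,1.37,0.93,0.71,1.23,0.95,0.62,1.46,0.93,0.66,1.3
activity_branch,Government,0.9,0.62,1.31,0.89,0.65,1.22,0.91,0.62,1.34,0.92,0.7,1.21,0.92,0.6,1.42,0.91,0.64,1.27
activity_branch,"Health, education, other social activities",0.95,0.65,1.39,0.95,0.69,1.3,0.96,0.65,1.41,0.97,0.73,1.27,0.98,0.64,1.5,0.96,0.68,1.35
activity_branch,Domestic housekeeping,0.92,0.53,1.6,0.94,0.61,1.44,0.91,0.52,1.59,0.96,0.56,1.41,0.93,0.5,1.74,0.94,0.57,1.54
activity_branch,Extraterritorial agencies,0.69,0.39,1.22,0.72,0.49,1.08,0.69,0.39,1.23,0.77,0.54,1.1,0.68,0.36,1.3,0.73,0.44,1.22
regime,Self-employed,0.65,0.61,0.69,0.79,0.76,0.82,0.64,0.6,0.68,0.8,0.78,0.83,0.58,0.54,0.62,0.71,0.67,0.75
entity,Insurance company,1.14,1.11,1.16,1.11,1.08,1.13,1.14,1.11,1.17,1.09,1.08,1.11,1.15,1.12,1.19,1.12,1.1,1.15
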