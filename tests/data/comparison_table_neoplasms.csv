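term,level,cfpm_rb,cfpm_rw,cpm_rb,cpm_rw,fpm_rb,fpm_rw,cm_rb,cm_rw,fm_rb,fm_rw
sex,Female,1.1,0.0,4.4,-14.3,1.1,-7.1,4.4,-28.6,-2.2,14.3
age_group,29-35,4.0,0.0,6.6,9.5,5.3,4.8,7.9,-4.8,0.0,19.1
age_group,36-45,3.8,-7.1,17.0,7.1,5.7,0.0,24.5,0.0,-3.8,7.1
age_group,>45,6.9,0.0,41.4,42.9,10.3,14.3,55.2,28.6,-10.3,14.3
health_region,Lleida,0.0,-2.5,4.6,-20.0,2.8,0.0,2.8,-35.0,-0.9,15.0
health_region,Camp de Tarragona,-2.5,-5.6,-7.4,-19.4,0.0,-2.8,-7.4,-30.6,10.7,33.3
health_region,Terres de l'Ebre,1.7,-3.8,7.7,-24.5,0.0,-1.9,4.3,-37.7,-2.6,13.2
health_region,Girona,2.3,-5.3,7.0,-15.8,2.3,0.0,7.0,-26.3,0.0,10.5
health_region,Catalunya Central,-1.1,-3.7,0.0,-22.2,0.0,-3.7,1.1,-29.6,0.0,14.8
health_region,Alt Pirineu i Aran,2.4,-1.3,14.3,-27.6,0.0,-1.3,14.3,-35.5,-6.0,10.5
activity_branch,"Manufacturing industry, energy production",-1.5,-5.0,2.9,-11.9,0.0,-1.0,7.4,-23.8,2.9,17.8
activity_branch,Construction,0.0,-3.6,12.7,-3.6,3.6,1.2,20.0,-16.9,0.0,14.5
activity_branch,Commercial/vehicles repair,0.0,-3.4,8.5,-6.8,3.4,2.3,15.3,-19.3,-1.7,12.5
activity_branch,"Hotel, restaurant businesses",0.0,-3.7,7.6,-7.4,1.9,0.0,15.1,-18.5,-1.9,12.4
activity_branch,Transportation/communication,0.0,-3.9,2.9,-10.7,2.9,1.9,8.8,-22.3,1.5,16.5
activity_branch,"Finance, real estate, services",0.0,-3.4,8.5,-5.7,1.7,1.1,15.3,-19.3,-3.4,12.5
activity_branch,Government,0.0,-3.4,6.8,-8.0,1.7,1.1,13.6,-19.3,0.0,15.9
activity_branch,"Health, education, other social activities",0.0,-3.3,6.6,-7.7,1.6,1.1,13.1,-19.8,1.6,16.5
activity_branch,Domestic housekeeping,0.0,-4.6,22.5,-15.7,2.0,0.0,32.7,-23.2,-10.2,10.2
activity_branch,Extraterritorial agencies,0.0,-2.9,46.4,-13.0,0.0,0.0,60.7,-18.8,-17.9,1.5
regime,Self-employed,2.8,-5.6,18.3,-27.8,-1.4,-5.6,21.1,-33.3,-15.5,-5.6
entity,Insurance company,0.0,-6.7,-1.9,-20.0,0.0,0.0,-2.9,-26.7,1.0,13.3
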