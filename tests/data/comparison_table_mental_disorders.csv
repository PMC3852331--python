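term,level,cfpm_rb,cfpm_rw,cpm_rb,cpm_rw,fpm_rb,fpm_rw,cm_rb,cm_rw,fm_rb,fm_rw
sex,Female,-1.1,25.0,1.1,0.0,-2.2,0.0,1.1,-25.0,-3.3,25.0
age_group,29-35,-1.2,0.0,1.2,-16.7,-1.2,0.0,3.5,-33.3,-3.5,16.7
age_group,36-45,-2.6,0.0,3.9,0.0,-2.6,0.0,5.1,-20.0,-6.4,0.0
age_group,>45,-4.6,0.0,6.1,0.0,-4.6,25.0,9.1,0.0,-10.6,25.0
health_region,Lleida,0.0,7.7,0.0,-15.4,-1.0,15.4,-1.0,-30.8,-1.0,15.4
health_region,Camp de Tarragona,1.9,10.0,-3.7,-10.0,2.8,10.0,-2.8,-20.0,8.4,40.0
health_region,Terres de l'Ebre,0.9,10.0,-1.9,-15.0,0.9,5.0,-2.8,-20.0,1.9,25.0
health_region,Girona,0.0,14.3,0.0,-14.3,0.0,14.3,0.0,-14.3,-1.0,28.6
health_region,Catalunya Central,1.0,11.1,-1.0,-11.1,1.0,11.1,-1.0,-22.2,1.0,22.2
health_region,Alt Pirineu i Aran,2.1,15.0,-2.1,-5.0,2.1,17.5,-3.1,-15.0,4.1,32.5
activity_branch,"Manufacturing industry, energy production",1.0,12.5,-3.9,-12.5,1.9,15.3,-1.9,-22.2,5.8,33.3
activity_branch,Construction,1.0,11.3,-2.0,-9.9,1.0,14.1,0.0,-19.7,4.0,31.0
activity_branch,Commercial/vehicles repair,0.0,11.3,-1.1,-9.7,0.0,12.9,2.3,-19.4,2.3,29.0
activity_branch,"Hotel, restaurant businesses",-1.1,11.3,-2.3,-9.7,-1.1,12.9,1.1,-19.4,1.1,29.0
activity_branch,Transportation/communication,-1.1,10.8,-2.2,-10.8,0.0,12.3,1.1,-20.0,2.2,27.7
activity_branch,"Finance, real estate, services",-1.1,12.5,-2.2,-9.4,0.0,15.6,0.0,-18.8,2.2,31.3
activity_branch,Government,-1.1,9.5,-2.2,-9.5,0.0,14.3,1.1,-19.1,1.1,30.2
activity_branch,"Health, education, other social activities",-1.0,10.5,-1.0,-9.0,0.0,13.4,1.0,-19.4,2.1,28.4
activity_branch,Domestic housekeeping,-2.1,10.3,0.0,-14.4,-3.2,10.3,2.1,-22.7,-1.1,27.8
activity_branch,Extraterritorial agencies,-5.5,6.4,-1.4,-24.4,-5.5,7.7,5.5,-28.2,-6.9,20.5
regime,Self-employed,-8.5,0.0,11.3,-25.0,-9.9,0.0,12.7,-37.5,-18.3,0.0
entity,Insurance company,1.8,0.0,-0.9,0.0,1.8,20.0,-2.7,-40.0,2.7,40.0
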